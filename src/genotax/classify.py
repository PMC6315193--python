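"""Classify a new genome against the clusters of a finished pipeline run."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .indexes import (
    compute_aai,
    compute_ani,
    distance_to_dddh,
    gbdp_distance,
    gbdp_hsp_stats,
)
from .io import gc_content, read_genome_fasta, read_proteome_fasta, read_sample_sheet
from .taxonomy import DelimitationThresholds, TaxonCluster, classify_new_genome


def _clusters_from_tsv(path: Path) -> tuple[list[TaxonCluster], list[TaxonCluster]]:
    df = pd.read_csv(path, sep="\t").fillna("")
    species: dict[int, set[str]] = {}
    genus: dict[int, set[str]] = {}
    for _, row in df.iterrows():
        species.setdefault(int(row["species_cluster"]), set()).add(row["genome_id"])
        if row["genus_cluster"] != "":
            genus.setdefault(int(row["genus_cluster"]), set()).add(row["genome_id"])
    mk = lambda rank, groups: [
        TaxonCluster(rank=rank, members=frozenset(m)) for _, m in sorted(groups.items())
    ]
    return mk("genus", genus), mk("species", species)


def classify_against_run(
    run_dir: Path,
    sample_sheet: Path,
    genome_path: Path,
    proteome_path: Path | None = None,
    query_id: str = "query",
    thresholds: DelimitationThresholds = DelimitationThresholds(),
) -> dict:
    """Compare a query genome to each cluster representative of an existing
    run and report the species/genus/novel verdict with all indexes used."""
    genus_clusters, species_clusters = _clusters_from_tsv(
        Path(run_dir) / "clusters.tsv"
    )
    entries = {e.id: e for e in read_sample_sheet(sample_sheet)}
    query = read_genome_fasta(genome_path, genome_id=query_id)
    query_prot = (
        read_proteome_fasta(proteome_path, query_id) if proteome_path else None
    )
    reps = {sorted(c.members)[0] for c in species_clusters}
    reps |= {sorted(c.members)[0] for c in genus_clusters}
    query_gc = gc_content(query)
    query_indexes: dict[str, dict[str, float | None]] = {}
    for rid in sorted(reps):
        entry = entries[rid]
        ref = read_genome_fasta(entry.genome_path, genome_id=rid)
        ani, _ = compute_ani(query, ref)
        stats = gbdp_hsp_stats(query, ref)
        dddh = distance_to_dddh(gbdp_distance(query, ref, formula="d6", stats=stats))
        aai = None
        if query_prot is not None and entry.proteome_path is not None:
            aai, _ = compute_aai(
                query_prot, read_proteome_fasta(entry.proteome_path, rid)
            )
        query_indexes[rid] = {
            "ani": ani,
            "dddh": dddh,
            "aai": aai,
            "gc_diff": abs(query_gc - gc_content(ref)),
        }
    return classify_new_genome(
        query_id, query_indexes, species_clusters, genus_clusters, thresholds
    )
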