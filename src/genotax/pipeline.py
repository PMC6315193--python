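"""End-to-end orchestration: indexes -> tree -> delimitation -> report.

A run is driven by a sample sheet (TSV: id, genome_path, proteome_path,
nomenclature metadata) and writes plain-text artifacts into an output
directory.  Every step records a manifest entry with SHA-256 checksums of
its inputs; re-running with unchanged inputs skips completed steps, and any
input change triggers recomputation of the affected step and everything
downstream.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import constants
from .indexes import (
    PairwiseComparison,
    PairwiseResults,
    all_pairwise,
    load_hsp_stats,
)
from .io import (
    GenomeRecord,
    ProteomeRecord,
    StrainMetadata,
    read_genome_fasta,
    read_proteome_fasta,
    read_sample_sheet,
)
from .phylo import (
    infer_tree,
    map_support,
    pseudo_bootstrap,
    read_newick,
    root_with_outgroup,
    write_newick,
    write_phylip,
)
from .taxonomy import (
    DelimitationThresholds,
    delimit_taxa,
    detect_phyly_problems,
    reclassification_actions,
    resolve_names,
)

logger = logging.getLogger(__name__)

ALL_STEPS = ("indexes", "tree", "delimit", "report")


@dataclass
class PipelineConfig:
    sample_sheet: Path
    output_dir: Path
    thresholds: DelimitationThresholds = field(default_factory=DelimitationThresholds)
    replicates: int = 100
    seed: int = 0
    outgroup: tuple[str, ...] = ()
    steps: tuple[str, ...] = ALL_STEPS
    tree_method: str = "bme"
    gbdp_formula: str = "d5"
    fragment_length: int = 1020

    def __post_init__(self) -> None:
        self.sample_sheet = Path(self.sample_sheet)
        self.output_dir = Path(self.output_dir)
        if not self.steps:
            raise ValueError("steps must be non-empty")
        for s in self.steps:
            if s not in ALL_STEPS:
                raise ValueError(f"unknown step {s!r}")

    def effective(self) -> dict:
        d = asdict(self)
        d["sample_sheet"] = str(self.sample_sheet)
        d["output_dir"] = str(self.output_dir)
        d["constants_version"] = constants.CONSTANTS_VERSION
        return d

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Build a config from a flat TOML file; keyword overrides win
        (the CLI passes its explicitly-set options through here).

        Recognized keys mirror the dataclass fields; thresholds live in a
        ``[thresholds]`` table.  The effective config is always written to
        the output directory, so a run is reproducible from its artifacts.
        """
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        thr = data.pop("thresholds", {})
        if thr and "thresholds" not in overrides:
            overrides["thresholds"] = DelimitationThresholds(**thr)
        for key in ("outgroup", "steps"):
            if key in data:
                data[key] = tuple(data[key])
        data.update(overrides)
        return cls(**data)


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sha256_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {}
        if path.exists():
            self.data = json.loads(path.read_text())

    def fresh(self, step: str, signature: str, outputs: list[Path]) -> bool:
        entry = self.data.get(step)
        return (
            entry is not None
            and entry["signature"] == signature
            and all(Path(o).exists() for o in entry["outputs"])
            and [str(o) for o in outputs] == entry["outputs"]
        )

    def record(self, step: str, signature: str, outputs: list[Path]) -> None:
        self.data[step] = {
            "signature": signature,
            "outputs": [str(o) for o in outputs],
        }
        self.path.write_text(json.dumps(self.data, indent=1))


def _load_inputs(config: PipelineConfig):
    entries = read_sample_sheet(config.sample_sheet)
    genomes: dict[str, GenomeRecord] = {}
    proteomes: dict[str, ProteomeRecord] = {}
    metadata: dict[str, StrainMetadata] = {}
    for e in entries:
        g = read_genome_fasta(e.genome_path, genome_id=e.id)
        g.metadata = e.metadata
        genomes[e.id] = g
        metadata[e.id] = e.metadata
        if e.proteome_path is not None:
            proteomes[e.id] = read_proteome_fasta(e.proteome_path, e.id)
    missing = [e.id for e in entries if e.proteome_path is None]
    if missing:
        logger.warning(
            "no proteome for %s: AAI/POCP absent, genus singletons flagged",
            ", ".join(missing),
        )
    return entries, genomes, proteomes, metadata


def _input_signature(config: PipelineConfig, entries) -> str:
    parts = [_sha256_file(config.sample_sheet)]
    for e in entries:
        parts.append(_sha256_file(e.genome_path))
        if e.proteome_path is not None:
            parts.append(_sha256_file(e.proteome_path))
    return _sha256_obj(parts)


def load_results(outdir: Path, gbdp_formula: str = "d5") -> PairwiseResults:
    """Rebuild a PairwiseResults from the indexes step's TSV artifacts."""
    outdir = Path(outdir)
    pairs = pd.read_csv(outdir / "pairs.tsv", sep="\t")
    per_genome = pd.read_csv(outdir / "gc.tsv", sep="\t").set_index("id")
    ids = list(per_genome.index)
    res = PairwiseResults(ids=ids, gbdp_formula=gbdp_formula)
    res.gc = {g: float(per_genome.loc[g, "gc_percent"]) for g in ids}
    res.genome_lengths = {
        g: int(per_genome.loc[g, "total_length"]) for g in ids
    }
    for _, row in pairs.iterrows():
        def val(col):
            v = row[col]
            return None if pd.isna(v) else float(v)

        comp = PairwiseComparison(
            genome_a=row["genome_a"],
            genome_b=row["genome_b"],
            ani=val("ani"),
            ani_fragments_used=int(row["ani_fragments_used"]),
            aai=val("aai"),
            aai_orthologs=int(row["aai_orthologs"]),
            pocp=val("pocp"),
            gbdp_distance=float(row["gbdp_distance"]),
            dddh=val("dddh"),
            gc_diff=val("gc_diff"),
        )
        res.comparisons[(comp.genome_a, comp.genome_b)] = comp
    res.hsp_stats = load_hsp_stats(outdir / "hsp_stats.tsv")
    return res


def run(config: PipelineConfig) -> dict:
    """Execute the requested steps in order; returns a summary dict."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    log_handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root_logger = logging.getLogger("genotax")
    root_logger.addHandler(log_handler)
    root_logger.setLevel(logging.INFO)
    try:
        return _run_steps(config)
    finally:
        root_logger.removeHandler(log_handler)
        log_handler.close()


def _run_steps(config: PipelineConfig) -> dict:
    out = config.output_dir
    (out / "config.json").write_text(json.dumps(config.effective(), indent=1))
    entries, genomes, proteomes, metadata = _load_inputs(config)
    manifest = _Manifest(out / "manifest.json")
    base_sig = _input_signature(config, entries)
    summary: dict = {"output_dir": str(out)}

    index_outputs = [
        out / n
        for n in (
            "ani.tsv",
            "aai.tsv",
            "pocp.tsv",
            "dddh.tsv",
            "gbdp_dist.tsv",
            "gc_diff.tsv",
            "pairs.tsv",
            "gc.tsv",
            "hsp_stats.tsv",
        )
    ]
    sig_indexes = _sha256_obj([base_sig, config.fragment_length, config.gbdp_formula])
    if "indexes" in config.steps:
        if manifest.fresh("indexes", sig_indexes, index_outputs):
            logger.info("indexes step up to date; skipping")
        else:
            logger.info(
                "computing pairwise indexes for %d genomes (thresholds: "
                "dDDH>=%.0f, ANI>=%.0f, AAI>=%.0f, dGC<%.1f)",
                len(genomes),
                config.thresholds.dddh_species_min,
                config.thresholds.ani_species_min,
                config.thresholds.aai_genus_min,
                config.thresholds.gc_diff_species_max,
            )
            res = all_pairwise(genomes, proteomes, gbdp_formula=config.gbdp_formula)
            res.write_tsvs(out)
            manifest.record("indexes", sig_indexes, index_outputs)

    tree_outputs = [out / "tree.nwk", out / "tree_support.nwk", out / "gbdp_dist.phylip"]
    sig_tree = _sha256_obj(
        [sig_indexes, config.replicates, config.seed, config.tree_method, list(config.outgroup)]
    )
    if "tree" in config.steps:
        if manifest.fresh("tree", sig_tree, tree_outputs):
            logger.info("tree step up to date; skipping")
        else:
            res = load_results(out, config.gbdp_formula)
            dm = res.distance_matrix()
            tree = infer_tree(dm, config.tree_method)
            replicates = pseudo_bootstrap(res, config.replicates, config.seed)
            rep_trees = [infer_tree(m, config.tree_method) for m in replicates]
            if config.outgroup:
                tree = root_with_outgroup(tree, list(config.outgroup))
            sup = map_support(tree, rep_trees)
            write_newick(tree, out / "tree.nwk")
            write_newick(sup, out / "tree_support.nwk")
            write_phylip(dm, out / "gbdp_dist.phylip")
            manifest.record("tree", sig_tree, tree_outputs)

    delimit_outputs = [out / "clusters.tsv", out / "phyly_report.tsv"]
    sig_delimit = _sha256_obj([sig_tree, asdict(config.thresholds)])
    if "delimit" in config.steps:
        if manifest.fresh("delimit", sig_delimit, delimit_outputs):
            logger.info("delimit step up to date; skipping")
        else:
            res = load_results(out, config.gbdp_formula)
            sup = read_newick(out / "tree_support.nwk")
            genus, species = delimit_taxa(
                sup, res, config.thresholds, outgroup=config.outgroup
            )
            genus = resolve_names(genus, metadata)
            species = resolve_names(species, metadata)
            actions = reclassification_actions(species, metadata)
            labels = {g: (metadata[g].name.split(" ")[0] if metadata[g].name else "") for g in res.ids}
            phyly = detect_phyly_problems(
                delimit_rooted_tree(sup, config.outgroup), labels
            )
            _write_clusters(out / "clusters.tsv", genus, species, actions)
            pd.DataFrame(
                sorted(phyly.items()), columns=["label", "phyly"]
            ).to_csv(out / "phyly_report.tsv", sep="\t", index=False)
            manifest.record("delimit", sig_delimit, delimit_outputs)
            summary["n_genus_clusters"] = len(genus)
            summary["n_species_clusters"] = len(species)

    if "report" in config.steps:
        text = report(out)
        (out / "report.md").write_text(text)
    return summary


def delimit_rooted_tree(tree, outgroup):
    """Root the support tree the same way the delimitation does."""
    if outgroup:
        return root_with_outgroup(tree, list(outgroup))
    return tree.root_at_midpoint()


def _write_clusters(path, genus, species, actions) -> None:
    genus_of: dict[str, int] = {}
    for gi, cl in enumerate(genus, 1):
        for g in cl.members:
            genus_of[g] = gi
    rows = []
    for si, cl in enumerate(species, 1):
        for g in sorted(cl.members):
            rows.append(
                {
                    "genome_id": g,
                    "species_cluster": si,
                    "genus_cluster": genus_of.get(g, ""),
                    "monophyletic": cl.monophyletic,
                    "resolved_name": cl.resolved_name or "",
                    "name_basis": cl.name_basis or "",
                    "action": actions.get(g, ""),
                    "synonyms": "; ".join(f"{j} -> {s}" for j, s in cl.synonyms),
                    "flags": ";".join(cl.flags),
                }
            )
    pd.DataFrame(rows).sort_values("genome_id").to_csv(path, sep="\t", index=False)


def report(run_dir: Path) -> str:
    """Human-readable summary: cluster memberships, phyly report,
    reclassification actions and per-cluster index ranges."""
    run_dir = Path(run_dir)
    clusters = pd.read_csv(run_dir / "clusters.tsv", sep="\t").fillna("")
    pairs = pd.read_csv(run_dir / "pairs.tsv", sep="\t")
    lines = ["# Genome-based taxonomic delimitation report", ""]
    n_genus = clusters["genus_cluster"].nunique()
    n_species = clusters["species_cluster"].nunique()
    lines.append(
        f"{len(clusters)} genomes in {n_genus} genus clusters and "
        f"{n_species} species clusters."
    )
    lines.append("")
    lines.append("## Species clusters")
    for si, grp in clusters.groupby("species_cluster"):
        members = ", ".join(sorted(grp["genome_id"]))
        name = grp["resolved_name"].iloc[0] or "(placeholder)"
        lines.append(f"- cluster {si}: {members} -> {name}")
        syn = grp["synonyms"].iloc[0]
        if isinstance(syn, str) and syn:
            lines.append(f"  - later heterotypic synonyms: {syn}")
    lines.append("")
    lines.append("## Genus clusters")
    for gi, grp in clusters.groupby("genus_cluster"):
        lines.append(f"- cluster {gi}: {', '.join(sorted(set(grp['genome_id'])))}")
        ids = set(grp["genome_id"])
        sub = pairs[pairs["genome_a"].isin(ids) & pairs["genome_b"].isin(ids)]
        if len(sub) and sub["aai"].notna().any():
            lines.append(
                f"  - in-clade AAI range {sub['aai'].min():.1f}-{sub['aai'].max():.1f}%, "
                f"dDDH {sub['dddh'].min():.1f}-{sub['dddh'].max():.1f}%"
            )
    phyly_path = run_dir / "phyly_report.tsv"
    if phyly_path.exists():
        phyly = pd.read_csv(phyly_path, sep="\t")
        if len(phyly):
            lines.append("")
            lines.append("## Phyly of input labels")
            for _, row in phyly.iterrows():
                lines.append(f"- {row['label']}: {row['phyly']}")
    lines.append("")
    lines.append("## Reclassification actions")
    for action, grp in clusters.groupby("action"):
        lines.append(f"- {action}: {', '.join(sorted(grp['genome_id']))}")
    return "\n".join(lines) + "\n"
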