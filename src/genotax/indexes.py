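"""Pairwise genome similarity indexes: ANI, AAI, POCP, GBDP distances, dDDH.

All indexes follow the fragment/RBH conventions of the comparative-genomics
literature: ANI is the fragment-based bidirectional procedure (1,020-bp
query fragments, 30% identity / 70% alignment-length retention, averaged
over both search directions); AAI is the mean identity over reciprocal best
protein hits; POCP is 2S/(T1+T2)*100; GBDP distances are computed from the
greedily trimmed, non-overlapping HSP set of whole-genome searches; dDDH is
a logistic transform of the identity distance (see :mod:`genotax.constants`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants
from .align import (
    ANI_FRAGMENT,
    GBDP_NUCLEOTIDE,
    PROTEIN_SEARCH,
    AlignParams,
    HSP,
    KmerIndex,
    batch_fragment_hits,
    local_align,
    reciprocal_best_hits,
)
from .io import GenomeRecord, ProteomeRecord, gc_content

logger = logging.getLogger(__name__)


@dataclass
class PairwiseComparison:
    """All similarity indexes for one (unordered) genome pair."""

    genome_a: str
    genome_b: str
    ani: float | None = None
    ani_fragments_used: int = 0
    aai: float | None = None
    aai_orthologs: int = 0
    pocp: float | None = None
    gbdp_distance: float = 0.0
    dddh: float | None = None
    gc_diff: float | None = None


# ---------------------------------------------------------------------------
# Genome fragmentation (ANI)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fragment:
    contig_index: int
    offset: int
    seq: str


def fragment_genome(
    genome: GenomeRecord, fragment_length: int = 1020, min_tail: int = 100
) -> list[Fragment]:
    """Cut every contig into consecutive non-overlapping windows.

    The trailing window of each contig is kept only when it is at least
    ``min_tail`` bases long, so fragment counts are deterministic.
    """
    if fragment_length <= 0:
        raise ValueError("fragment_length must be positive")
    fragments: list[Fragment] = []
    for ci, contig in enumerate(genome.contigs):
        for off in range(0, len(contig), fragment_length):
            piece = contig[off : off + fragment_length]
            if len(piece) == fragment_length or len(piece) >= min_tail:
                fragments.append(Fragment(ci, off, piece))
    return fragments


# ---------------------------------------------------------------------------
# ANI
# ---------------------------------------------------------------------------


def ani_one_direction(
    query: GenomeRecord,
    reference: GenomeRecord,
    params: AlignParams = ANI_FRAGMENT,
    min_identity: float = 30.0,
    min_coverage: float = 0.70,
    fragment_length: int = 1020,
    reference_index: KmerIndex | None = None,
    seed_matches=None,
) -> tuple[float | None, int]:
    """One search direction of the fragment-based ANI procedure.

    Each query fragment's best placement on the reference is retained iff it
    passes the E-value filter, has identity >= ``min_identity`` percent and
    aligns over at least ``min_coverage`` of the fragment.  Returns the mean
    percent identity over retained fragments and their count; (None, 0) when
    nothing is retained.
    """
    index = reference_index or KmerIndex(
        reference.sequence, params.kmer_size, params.max_kmer_occ
    )
    contig_start = np.concatenate(
        ([0], np.cumsum([len(c) for c in query.contigs])[:-1])
    )
    frags = [
        (int(contig_start[f.contig_index] + f.offset), f.seq)
        for f in fragment_genome(query, fragment_length)
    ]
    idents: list[float] = []
    for (off, seq), hsp in zip(
        frags,
        batch_fragment_hits(frags, query.sequence, index, params, seed_matches),
    ):
        if hsp is None:
            continue
        if hsp.pident >= min_identity and hsp.length >= min_coverage * len(seq):
            idents.append(hsp.pident)
    if not idents:
        logger.info(
            "ANI %s->%s undefined: no fragment retained", query.id, reference.id
        )
        return None, 0
    return float(np.mean(idents)), len(idents)


def compute_ani(
    a: GenomeRecord,
    b: GenomeRecord,
    params: AlignParams = ANI_FRAGMENT,
    index_a: KmerIndex | None = None,
    index_b: KmerIndex | None = None,
    seeds_ab=None,
    seeds_ba=None,
    **kwargs,
) -> tuple[float | None, int]:
    """Bidirectional ANI: mean of the two directional means (symmetric by
    construction).  Returns (ani or None, total fragments used)."""
    ab, n_ab = ani_one_direction(
        a, b, params, reference_index=index_b, seed_matches=seeds_ab, **kwargs
    )
    ba, n_ba = ani_one_direction(
        b, a, params, reference_index=index_a, seed_matches=seeds_ba, **kwargs
    )
    if ab is None or ba is None:
        return None, n_ab + n_ba
    return (ab + ba) / 2.0, n_ab + n_ba


# ---------------------------------------------------------------------------
# AAI and POCP
# ---------------------------------------------------------------------------


def compute_aai(
    a: ProteomeRecord,
    b: ProteomeRecord,
    params: AlignParams = PROTEIN_SEARCH,
    min_identity: float = 30.0,
    min_coverage: float = 0.70,
    profile_a=None,
    profile_b=None,
) -> tuple[float | None, int]:
    """AAI = mean percent identity over reciprocal best hits; the ortholog
    count doubles as S in the POCP formula.  (None, 0) with no orthologs."""
    pairs = reciprocal_best_hits(
        a, b, params, min_identity, min_coverage, profile_a, profile_b
    )
    if not pairs:
        return None, 0
    return float(np.mean([p[2] for p in pairs])), len(pairs)


def compute_pocp_one_directional(
    a: ProteomeRecord,
    b: ProteomeRecord,
    params: AlignParams = PROTEIN_SEARCH,
    min_identity: float = 30.0,
    min_coverage: float = 0.70,
) -> float:
    """POCP with per-direction conserved-protein counts, (C1+C2)/(T1+T2)*100.

    This variant (off by default; the pipeline uses the reciprocal-best-hit
    S) counts every protein with a qualifying hit in the other proteome,
    matching the original definition of the statistic.
    """
    from .align import qualifying_hit_counts

    c1, c2 = qualifying_hit_counts(a, b, params, min_identity, min_coverage)
    return (c1 + c2) / (a.count + b.count) * 100


def compute_pocp(a: ProteomeRecord, b: ProteomeRecord, shared: int) -> float:
    """Percentage of conserved proteins: (2*S)/(T1+T2)*100, exact arithmetic."""
    if a.count <= 0 or b.count <= 0:
        raise ValueError("both proteomes must be non-empty")
    if shared > min(a.count, b.count):
        raise ValueError(
            f"shared ortholog count {shared} exceeds smaller proteome "
            f"({min(a.count, b.count)})"
        )
    return 2 * shared / (a.count + b.count) * 100


# ---------------------------------------------------------------------------
# GBDP: greedy trimming and distance formulas
# ---------------------------------------------------------------------------


class _IntervalSet:
    """Sorted, disjoint covered intervals; supports overlap query and add."""

    def __init__(self) -> None:
        self._iv: list[tuple[int, int]] = []

    def overlap(self, start: int, end: int) -> int:
        return sum(
            max(0, min(end, e) - max(start, s)) for s, e in self._iv
        )

    def add(self, start: int, end: int) -> None:
        merged = [(start, end)]
        for s, e in self._iv:
            if s <= merged[0][1] and e >= merged[0][0]:
                merged[0] = (min(merged[0][0], s), max(merged[0][1], e))
            else:
                merged.append((s, e))
        self._iv = sorted(merged)


def greedy_trim(hsps: list[HSP]) -> list[tuple[int, int]]:
    """Reduce HSPs to a non-overlapping set by greedy selection with trimming.

    HSPs are visited in descending bit-score order (ties by coordinates).
    An HSP overlapping already-covered query or subject regions by more than
    half its span is dropped; smaller overlaps are trimmed away by scaling
    length and identities proportionally.  Returns (identities, length)
    pairs of the retained set — the quantities every distance formula needs.
    """
    q_cov = _IntervalSet()
    s_cov = _IntervalSet()
    retained: list[tuple[int, int]] = []
    for h in sorted(hsps, key=lambda h: (-h.bitscore, h.q_start, h.s_start)):
        q_len = h.q_end - h.q_start
        s_len = h.s_end - h.s_start
        if q_len <= 0 or s_len <= 0:
            continue
        frac = max(
            q_cov.overlap(h.q_start, h.q_end) / q_len,
            s_cov.overlap(h.s_start, h.s_end) / s_len,
        )
        if frac > 0.5:
            continue
        keep = 1.0 - frac
        length = max(1, round(h.length * keep))
        ident = min(length, round(h.identities * keep))
        retained.append((ident, length))
        q_cov.add(h.q_start, h.q_end)
        s_cov.add(h.s_start, h.s_end)
    return retained


def gbdp_hsp_stats(
    a: GenomeRecord,
    b: GenomeRecord,
    params: AlignParams = GBDP_NUCLEOTIDE,
    index_a: KmerIndex | None = None,
    index_b: KmerIndex | None = None,
) -> list[list[tuple[int, int]]]:
    """Trimmed (identities, length) HSP statistics for both search
    directions of a genome pair; the resampling units of the bootstrap."""
    ab = local_align(a.sequence, b.sequence, params, a.id, b.id, subject_index=index_b)
    ba = local_align(b.sequence, a.sequence, params, b.id, a.id, subject_index=index_a)
    return [greedy_trim(ab), greedy_trim(ba)]


def distance_from_stats(
    stats: list[tuple[int, int]],
    len_a: int,
    len_b: int,
    formula: str = "d5",
) -> float:
    """One GBDP distance from a retained HSP set (one search direction)."""
    if formula not in constants.GBDP_FORMULAS:
        raise ValueError(f"unknown GBDP formula {formula!r}")
    cap = constants.GBDP_MAX_DISTANCE[formula]
    total_id = sum(i for i, _ in stats)
    total_len = sum(l for _, l in stats)
    if total_len == 0 or total_id == 0:
        return cap
    if formula == "d0":
        return max(0.0, 1.0 - 2.0 * total_len / (len_a + len_b))
    if formula == "d4":
        return min(cap, -math.log(min(1.0, 2.0 * total_len / (len_a + len_b))))
    if formula == "d6":
        return 1.0 - total_id / total_len
    return min(cap, -math.log(total_id / total_len))  # d5


def gbdp_distance(
    a: GenomeRecord,
    b: GenomeRecord,
    params: AlignParams = GBDP_NUCLEOTIDE,
    formula: str = "d5",
    stats: list[list[tuple[int, int]]] | None = None,
    **kwargs,
) -> float:
    """Symmetric GBDP distance: mean of the two directional distances.

    ``stats`` may carry precomputed :func:`gbdp_hsp_stats` output to avoid
    re-alignment.  A pair with no HSP at all reports the formula's capped
    maximum (flagged in the log).
    """
    if a.id == b.id and a.contigs == b.contigs:
        return 0.0
    if stats is None:
        stats = gbdp_hsp_stats(a, b, params, **kwargs)
    if not stats[0] and not stats[1]:
        logger.warning("no HSPs between %s and %s: distance capped", a.id, b.id)
    la, lb = a.total_length, b.total_length
    d_ab = distance_from_stats(stats[0], la, lb, formula)
    d_ba = distance_from_stats(stats[1], lb, la, formula)
    return (d_ab + d_ba) / 2.0


def distance_to_dddh(d: float) -> float:
    """dDDH percentage from an identity distance (see constants module);
    strictly monotone decreasing, range (0, 100)."""
    return constants.dddh_from_distance(d)


# ---------------------------------------------------------------------------
# Batch computation
# ---------------------------------------------------------------------------


@dataclass
class PairwiseResults:
    """All pairwise comparisons of a genome set plus bootstrap material."""

    ids: list[str]
    comparisons: dict[tuple[str, str], PairwiseComparison] = field(default_factory=dict)
    #: per ordered-pair trimmed HSP stats, for the pseudo-bootstrap
    hsp_stats: dict[tuple[str, str], list[list[tuple[int, int]]]] = field(
        default_factory=dict
    )
    genome_lengths: dict[str, int] = field(default_factory=dict)
    gc: dict[str, float] = field(default_factory=dict)
    gbdp_formula: str = "d5"

    def get(self, a: str, b: str) -> PairwiseComparison:
        key = (a, b) if (a, b) in self.comparisons else (b, a)
        return self.comparisons[key]

    def matrix(self, index: str) -> pd.DataFrame:
        """Symmetric DataFrame of one index ('ani', 'aai', 'pocp', 'dddh',
        'gbdp_distance', 'gc_diff')."""
        diag = {
            "ani": 100.0,
            "aai": 100.0,
            "pocp": 100.0,
            "dddh": distance_to_dddh(0.0),
            "gbdp_distance": 0.0,
            "gc_diff": 0.0,
        }[index]
        n = len(self.ids)
        mat = np.full((n, n), np.nan)
        np.fill_diagonal(mat, diag)
        pos = {g: i for i, g in enumerate(self.ids)}
        for (a, b), comp in self.comparisons.items():
            v = getattr(comp, index)
            if v is None:
                v = np.nan
            mat[pos[a], pos[b]] = v
            mat[pos[b], pos[a]] = v
        return pd.DataFrame(mat, index=self.ids, columns=self.ids)

    def distance_matrix(self) -> pd.DataFrame:
        """GBDP distance matrix with NaN-free entries (missing pairs capped)."""
        df = self.matrix("gbdp_distance")
        return df.fillna(constants.GBDP_MAX_DISTANCE[self.gbdp_formula])

    def long_table(self) -> pd.DataFrame:
        rows = []
        for (a, b), c in sorted(self.comparisons.items()):
            rows.append(
                {
                    "genome_a": a,
                    "genome_b": b,
                    "ani": c.ani,
                    "ani_fragments_used": c.ani_fragments_used,
                    "aai": c.aai,
                    "aai_orthologs": c.aai_orthologs,
                    "pocp": c.pocp,
                    "gbdp_distance": c.gbdp_distance,
                    "dddh": c.dddh,
                    "gc_diff": c.gc_diff,
                }
            )
        return pd.DataFrame(rows)

    def write_tsvs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        names = {
            "ani": "ani.tsv",
            "aai": "aai.tsv",
            "pocp": "pocp.tsv",
            "dddh": "dddh.tsv",
            "gbdp_distance": "gbdp_dist.tsv",
            "gc_diff": "gc_diff.tsv",
        }
        for index, fname in names.items():
            self.matrix(index).to_csv(outdir / fname, sep="\t", float_format="%.4f")
        self.long_table().to_csv(outdir / "pairs.tsv", sep="\t", index=False, float_format="%.4f")
        pd.DataFrame(
            {
                "id": list(self.gc),
                "gc_percent": [round(self.gc[g], 2) for g in self.gc],
                "total_length": [self.genome_lengths.get(g, 0) for g in self.gc],
            }
        ).to_csv(outdir / "gc.tsv", sep="\t", index=False)
        # HSP stats for resumable bootstrap
        rows = []
        for (a, b), directions in sorted(self.hsp_stats.items()):
            for d, stats in enumerate(directions):
                for ident, length in stats:
                    rows.append((a, b, d, ident, length))
        pd.DataFrame(
            rows, columns=["genome_a", "genome_b", "direction", "identities", "length"]
        ).to_csv(outdir / "hsp_stats.tsv", sep="\t", index=False)


def load_hsp_stats(path: str | Path) -> dict[tuple[str, str], list[list[tuple[int, int]]]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[tuple[str, str], list[list[tuple[int, int]]]] = {}
    for (a, b), grp in df.groupby(["genome_a", "genome_b"], sort=True):
        dirs: list[list[tuple[int, int]]] = [[], []]
        for _, row in grp.iterrows():
            dirs[int(row["direction"])].append((int(row["identities"]), int(row["length"])))
        out[(a, b)] = dirs
    return out


def all_pairwise(
    genomes: dict[str, GenomeRecord],
    proteomes: dict[str, ProteomeRecord] | None = None,
    nuc_params: AlignParams = GBDP_NUCLEOTIDE,
    ani_params: AlignParams = ANI_FRAGMENT,
    prot_params: AlignParams = PROTEIN_SEARCH,
    gbdp_formula: str = "d5",
) -> PairwiseResults:
    """Compute every unordered pairwise comparison of a genome set.

    Per-pair failures (e.g. undefined ANI between unrelated genomes) are
    recorded as absent values and never abort the batch.  Proteome-dependent
    indexes are absent for genomes without a proteome.
    """
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    proteomes = proteomes or {}
    ids = list(genomes)
    res = PairwiseResults(ids=ids, gbdp_formula=gbdp_formula)
    res.genome_lengths = {g: genomes[g].total_length for g in ids}
    for g in ids:
        res.gc[g] = gc_content(genomes[g])
    from .align import ProteomeProfile  # deferred: keep module import light

    indexes = {
        g: KmerIndex(genomes[g].sequence, nuc_params.kmer_size, nuc_params.max_kmer_occ)
        for g in ids
    }
    profiles = {
        g: ProteomeProfile(proteomes[g], prot_params) for g in ids if g in proteomes
    }
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ga, gb = genomes[a], genomes[b]
            comp = PairwiseComparison(genome_a=a, genome_b=b)
            comp.gc_diff = abs(res.gc[a] - res.gc[b])
            # one seed scan per ordered pair and strand, shared between the
            # ANI fragment search and the GBDP whole-genome search (the
            # presets use identical seeding)
            seeds_ab = {s: indexes[b].matches(ga.sequence, s) for s in "+-"}
            seeds_ba = {s: indexes[a].matches(gb.sequence, s) for s in "+-"}
            comp.ani, comp.ani_fragments_used = compute_ani(
                ga,
                gb,
                ani_params,
                index_a=indexes[a],
                index_b=indexes[b],
                seeds_ab=seeds_ab,
                seeds_ba=seeds_ba,
            )
            hsp_ab = local_align(
                ga.sequence, gb.sequence, nuc_params, a, b,
                subject_index=indexes[b], seed_matches=seeds_ab,
            )
            hsp_ba = local_align(
                gb.sequence, ga.sequence, nuc_params, b, a,
                subject_index=indexes[a], seed_matches=seeds_ba,
            )
            stats = [greedy_trim(hsp_ab), greedy_trim(hsp_ba)]
            res.hsp_stats[(a, b)] = stats
            comp.gbdp_distance = gbdp_distance(ga, gb, nuc_params, gbdp_formula, stats=stats)
            d_ident = gbdp_distance(ga, gb, nuc_params, "d6", stats=stats)
            comp.dddh = distance_to_dddh(d_ident)
            if a in proteomes and b in proteomes:
                comp.aai, comp.aai_orthologs = compute_aai(
                    proteomes[a],
                    proteomes[b],
                    prot_params,
                    profile_a=profiles[a],
                    profile_b=profiles[b],
                )
                comp.pocp = compute_pocp(proteomes[a], proteomes[b], comp.aai_orthologs)
            res.comparisons[(a, b)] = comp
    return res
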