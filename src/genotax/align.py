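"""Local-alignment machinery: HSP generation, fragment mapping, reciprocal
best hits.

This is the package's replacement for the BLASTN/BLASTP/DIAMOND searches a
genome-taxonomy pipeline normally shells out to.  Nucleotide searches use
k-mer diagonal seeding followed by bounded alignment (edlib) of the seeded
region; protein searches use shared-k-mer candidate filtering followed by
optimal local alignment (Biopython's PairwiseAligner with BLOSUM62).  The
contract is statistical agreement with BLAST-style output (identities,
lengths, E-value filtering), not bit-identical HSP sets.

Coordinates are 0-based half-open on forward strands everywhere; a
minus-strand HSP stores forward-strand subject coordinates plus a strand
flag.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from . import constants
from .io import ProteomeRecord

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignParams:
    """Scoring and seeding parameters for one search preset."""

    mode: str = "nucleotide"  # nucleotide | protein
    kmer_size: int = 11
    min_seed_hits: int = 2
    band_width: int = 24  # diagonal tolerance when clustering seeds
    max_gap: int = 600  # max seed-free stretch inside one segment
    chunk_size: int = 3000  # long diagonal runs are aligned in chunks
    pad: int = 30  # slack added around seeded regions
    max_kmer_occ: int = 50  # repeat masking: ignore over-frequent k-mers
    x_drop: float = 20.0  # retained for API compatibility; extension is
    # bounded by the seeded region rather than score drop-off
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    evalue_cutoff: float = 1e-8
    protein_matrix: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        floor = 2 if self.mode == "protein" else 4
        if self.kmer_size < floor:
            raise ValueError(f"kmer_size must be >= {floor} in {self.mode} mode")

    @property
    def karlin_lambda(self) -> float:
        return constants.PROT_LAMBDA if self.mode == "protein" else constants.NUC_LAMBDA

    @property
    def karlin_k(self) -> float:
        return constants.PROT_K if self.mode == "protein" else constants.NUC_K


#: GBDP whole-genome search: BLASTN-style scores, E <= 1e-8.
GBDP_NUCLEOTIDE = AlignParams(evalue_cutoff=1e-8)
#: ANI fragment search: same scores, stricter E filter.
ANI_FRAGMENT = AlignParams(evalue_cutoff=1e-15, min_seed_hits=2)
#: Proteome search: BLOSUM62 gap 11/1, E <= 1e-5, 3-mer candidate seeding.
PROTEIN_SEARCH = AlignParams(
    mode="protein",
    kmer_size=3,
    min_seed_hits=25,
    gap_open=-11,
    gap_extend=-1,
    evalue_cutoff=1e-5,
)


@dataclass
class HSP:
    """A local alignment segment pair."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str  # "+" or "-": subject orientation
    length: int  # aligned columns (incl. gaps)
    identities: int
    mismatches: int = 0
    gap_opens: int = 0
    gaps: int = 0
    raw_score: float = 0.0
    bitscore: float = 0.0
    evalue: float = math.inf

    @property
    def pident(self) -> float:
        return 100.0 * self.identities / self.length if self.length else 0.0


def bitscore(raw_score: float, params: AlignParams) -> float:
    """Bit score from a raw alignment score under the preset's statistics."""
    return (params.karlin_lambda * raw_score - math.log(params.karlin_k)) / math.log(2)


def evalue(bits: float, query_len: int, subject_len: int) -> float:
    """Karlin-Altschul style expectation: E = m * n * 2**(-bitscore)."""
    if query_len <= 0 or subject_len <= 0:
        raise ValueError("sequence lengths must be positive")
    # work in log space to avoid overflow for huge bit scores
    log_e = math.log(query_len) + math.log(subject_len) - bits * math.log(2)
    return math.exp(log_e) if log_e < 700 else math.inf


# ---------------------------------------------------------------------------
# k-mer index and seeding
# ---------------------------------------------------------------------------


_NT_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _NT_CODE_LUT[ord(_b)] = _i


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, integer codes) of all k-mers made purely of A/C/G/T."""
    codes = _NT_CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win < 4).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = win.astype(np.int64) @ powers
    pos = np.nonzero(valid)[0]
    return pos, vals[valid]


class KmerIndex:
    """Sorted-array k-mer index of a sequence, on both strands.

    Built once per reference genome and reused by every search against it;
    lookups are vectorized binary searches.  Query k-mers matching more
    than ``max_occ`` reference positions are dropped as repeats.
    """

    def __init__(self, seq: str, k: int = 11, max_occ: int = 50):
        self.seq = seq
        self.k = k
        self.max_occ = max_occ
        self.rc_seq = revcomp(seq)
        self._fwd = self._build(seq)
        self._rev = self._build(self.rc_seq)

    def _build(self, seq: str):
        pos, codes = _kmer_codes(seq, self.k)
        order = np.argsort(codes, kind="stable")
        return codes[order], pos[order]

    def matches(self, query: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        """(query_pos, subject_pos) arrays of exact k-mer matches."""
        sorted_codes, sorted_pos = self._fwd if strand == "+" else self._rev
        qpos, qcodes = _kmer_codes(query, self.k)
        if qpos.size == 0 or sorted_codes.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        lo = np.searchsorted(sorted_codes, qcodes, side="left")
        hi = np.searchsorted(sorted_codes, qcodes, side="right")
        counts = hi - lo
        keep = (counts > 0) & (counts <= self.max_occ)
        lo, cnt, qp = lo[keep], counts[keep], qpos[keep]
        total = int(cnt.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        # expand [lo, lo+cnt) ranges into flat indices
        starts = np.repeat(lo - np.concatenate(([0], cnt[:-1])).cumsum(), cnt)
        flat = starts + np.arange(total)
        return np.repeat(qp, cnt), sorted_pos[flat]


def _cluster_seeds(
    qpos: np.ndarray, spos: np.ndarray, params: AlignParams
) -> list[tuple[int, int, int]]:
    """Group seed matches into per-diagonal runs; return (diag, q0, q1).

    Seeds are sorted by (diagonal, query position); a run breaks when the
    diagonal changes or the seed-free query stretch exceeds ``max_gap``.
    Runs with fewer than ``min_seed_hits`` seeds are discarded.  Indels
    shift the diagonal, so each inter-indel stretch yields its own run.
    """
    if qpos.size == 0:
        return []
    diag = spos - qpos
    order = np.lexsort((qpos, diag))
    diag = diag[order]
    q = qpos[order]
    k = params.kmer_size
    # runs of seeds on one exact diagonal, split at query gaps (vectorized)
    brk = (diag[1:] != diag[:-1]) | (q[1:] - q[:-1] > params.max_gap)
    starts = np.concatenate(([0], np.nonzero(brk)[0] + 1))
    ends = np.concatenate((starts[1:], [len(q)]))
    keep = (ends - starts) >= params.min_seed_hits
    return [
        (int(diag[s]), int(q[s]), int(q[e - 1]) + k)
        for s, e in zip(starts[keep], ends[keep])
    ]


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _score_ops(ops: Iterable[tuple[int, str]], params: AlignParams):
    """(raw, columns, identities, mismatches, gap_opens, gaps, q_span, s_span)."""
    raw = 0.0
    cols = ident = mism = gopen = gaps = qspan = sspan = 0
    for n, op in ops:
        cols += n
        if op == "=":
            ident += n
            raw += params.match * n
            qspan += n
            sspan += n
        elif op in "XM":
            mism += n
            raw += params.mismatch * n
            qspan += n
            sspan += n
        else:  # I or D
            gopen += 1
            gaps += n
            raw += params.gap_open + params.gap_extend * n
            if op == "I":
                qspan += n
            else:
                sspan += n
    return raw, cols, ident, mism, gopen, gaps, qspan, sspan


def _ungapped_hsp(
    query_arr: np.ndarray,
    subject_arr: np.ndarray,
    d: int,
    q0: int,
    q1: int,
    params: AlignParams,
    ext_left: int = 0,
    ext_right: int = 0,
) -> tuple[int, int, int, float] | None:
    """Best-scoring ungapped segment on diagonal ``d`` around query[q0:q1].

    The seeded run is first widened by the allowed extensions (clipped to
    the diagonal's extent), then the maximal-scoring sub-segment under the
    match/mismatch scores is located on the column-wise comparison.  Returns
    (q_start, q_end, identities, raw_score) or None when no positive-scoring
    segment exists.  HSPs produced this way are gap-free, as in classic
    ungapped BLAST extension; indel events split homology into several HSPs
    on shifted diagonals.
    """
    lo = max(0, q0 - ext_left, -d)
    hi = min(len(query_arr), q1 + ext_right, len(subject_arr) - d)
    if hi <= lo:
        return None
    eq = query_arr[lo:hi] == subject_arr[lo + d : hi + d]
    scores = np.where(eq, float(params.match), float(params.mismatch))
    prefix = np.concatenate(([0.0], np.cumsum(scores)))
    run_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - run_min
    j = int(np.argmax(gains))
    best = float(gains[j])
    if best <= 0:
        return None
    i = int(np.argmin(prefix[: j + 1]))
    ident = int(eq[i : j + 1].sum())
    return lo + i, lo + j + 1, ident, best


def local_align(
    query: str,
    subject: str,
    params: AlignParams = GBDP_NUCLEOTIDE,
    query_id: str = "query",
    subject_id: str = "subject",
    subject_index: KmerIndex | None = None,
    seed_matches: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> list[HSP]:
    """Seed-and-extend local alignment; returns E-value-filtered HSPs sorted
    by descending bit score (ties broken by (q_start, s_start)).

    In nucleotide mode both subject strands are searched.  Sequences shorter
    than the k-mer size yield an empty result.  A prebuilt
    :class:`KmerIndex` of the subject may be supplied to amortize indexing
    across searches.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    if params.mode == "protein":
        hsp = align_protein_pair(query, subject, params, query_id, subject_id)
        return [hsp] if hsp is not None and hsp.evalue <= params.evalue_cutoff else []

    if len(query) < params.kmer_size or len(subject) < params.kmer_size:
        return []
    index = subject_index or KmerIndex(subject, params.kmer_size, params.max_kmer_occ)
    if index.k != params.kmer_size:
        raise ValueError("subject_index k-mer size does not match params")
    m, n = len(query), len(subject)
    query_arr = np.frombuffer(query.encode(), dtype=np.uint8)
    hsps: list[HSP] = []
    for strand in "+-":
        subj = index.seq if strand == "+" else index.rc_seq
        subj_arr = np.frombuffer(subj.encode(), dtype=np.uint8)
        if seed_matches is not None:
            qpos, spos = seed_matches[strand]
        else:
            qpos, spos = index.matches(query, strand)
        for d, q0, q1 in _cluster_seeds(qpos, spos, params):
            # long runs are scored in chunks so every HSP stays a bounded
            # resampling unit for the pseudo-bootstrap; seed-free margin is
            # explored only at the run's outer edges
            nchunks = max(1, math.ceil((q1 - q0) / params.chunk_size))
            step = math.ceil((q1 - q0) / nchunks)
            for c in range(nchunks):
                cq0 = q0 + c * step
                cq1 = q1 if c == nchunks - 1 else min(q1, cq0 + step)
                if cq1 <= cq0:
                    continue
                got = _ungapped_hsp(
                    query_arr,
                    subj_arr,
                    d,
                    cq0,
                    cq1,
                    params,
                    ext_left=params.max_gap if c == 0 else 0,
                    ext_right=params.max_gap if c == nchunks - 1 else 0,
                )
                if got is None:
                    continue
                aq0, aq1, ident, raw = got
                cols = aq1 - aq0
                bits = bitscore(raw, params)
                ev = evalue(bits, m, n)
                if ev > params.evalue_cutoff:
                    continue
                as0 = aq0 + d
                if strand == "+":
                    ss, se = as0, as0 + cols
                else:
                    ss, se = len(subj) - (as0 + cols), len(subj) - as0
                hsps.append(
                    HSP(
                        query_id=query_id,
                        subject_id=subject_id,
                        q_start=aq0,
                        q_end=aq1,
                        s_start=ss,
                        s_end=se,
                        strand=strand,
                        length=cols,
                        identities=ident,
                        mismatches=cols - ident,
                        gap_opens=0,
                        gaps=0,
                        raw_score=raw,
                        bitscore=bits,
                        evalue=ev,
                    )
                )
    hsps.sort(key=lambda h: (-h.bitscore, h.q_start, h.s_start))
    return hsps


# ---------------------------------------------------------------------------
# Fragment mapping (ANI search path)
# ---------------------------------------------------------------------------


def _strand_fragment_hit(
    fragment: str,
    index: KmerIndex,
    strand: str,
    qpos: np.ndarray,
    spos: np.ndarray,
    params: AlignParams,
) -> HSP | None:
    """Place one fragment on one reference strand given its seed matches.

    Seeds vote for a diagonal band; the fragment is then aligned
    semi-globally (edlib infix mode) against the winning window, so the
    whole fragment is consumed and identity reflects every column.
    """
    if qpos.size == 0:
        return None
    flen = len(fragment)
    diag = spos - qpos
    # vote on coarse diagonal buckets; ties resolved toward lower diagonal
    buckets, counts = np.unique(diag // 64, return_counts=True)
    if counts.max() < params.min_seed_hits:
        return None
    top = buckets[np.argmax(counts)]
    sel = (diag // 64 >= top - 1) & (diag // 64 <= top + 1)
    d_lo, d_hi = int(diag[sel].min()), int(diag[sel].max())
    subj = index.seq if strand == "+" else index.rc_seq
    if d_lo == d_hi and 0 <= d_lo and d_lo + flen <= len(subj):
        # all seeds on one diagonal: the placement is gap-free, so score the
        # column-wise comparison directly (no banded alignment needed)
        eq = np.frombuffer(fragment.encode(), dtype=np.uint8) == np.frombuffer(
            subj[d_lo : d_lo + flen].encode(), dtype=np.uint8
        )
        ident = int(eq.sum())
        mism = flen - ident
        cols = qspan = sspan = flen
        gopen = gaps = 0
        raw = params.match * ident + params.mismatch * mism
        as0 = d_lo
        if raw <= 0:
            return None
        bits = bitscore(raw, params)
        ev = evalue(bits, flen, len(index.seq))
        if strand == "+":
            ss, se = as0, as0 + sspan
        else:
            ss, se = len(subj) - (as0 + sspan), len(subj) - as0
        return HSP(
            query_id="fragment",
            subject_id="reference",
            q_start=0,
            q_end=flen,
            s_start=ss,
            s_end=se,
            strand=strand,
            length=cols,
            identities=ident,
            mismatches=mism,
            raw_score=raw,
            bitscore=bits,
            evalue=ev,
        )
    w0 = max(0, d_lo - params.pad)
    w1 = min(len(subj), d_hi + flen + params.pad)
    if w1 <= w0:
        return None
    res = edlib.align(fragment, subj[w0:w1], mode="HW", task="path")
    if res["cigar"] is None:
        return None
    ops = _parse_cigar(res["cigar"])
    raw, cols, ident, mism, gopen, gaps, qspan, sspan = _score_ops(ops, params)
    if raw <= 0:
        return None
    bits = bitscore(raw, params)
    ev = evalue(bits, flen, len(index.seq))
    as0 = w0 + res["locations"][0][0]
    if strand == "+":
        ss, se = as0, as0 + sspan
    else:
        ss, se = len(subj) - (as0 + sspan), len(subj) - as0
    return HSP(
        query_id="fragment",
        subject_id="reference",
        q_start=0,
        q_end=flen,
        s_start=ss,
        s_end=se,
        strand=strand,
        length=cols,
        identities=ident,
        mismatches=mism,
        gap_opens=gopen,
        gaps=gaps,
        raw_score=raw,
        bitscore=bits,
        evalue=ev,
    )


def best_fragment_hit(
    fragment: str, index: KmerIndex, params: AlignParams = ANI_FRAGMENT
) -> HSP | None:
    """Best placement of one query fragment on an indexed reference (both
    strands searched).  None when no strand produces enough seeds or the
    E-value filter fails."""
    best: HSP | None = None
    for strand in "+-":
        qpos, spos = index.matches(fragment, strand)
        hsp = _strand_fragment_hit(fragment, index, strand, qpos, spos, params)
        if hsp is not None and (best is None or hsp.raw_score > best.raw_score):
            best = hsp
    if best is None or best.evalue > params.evalue_cutoff:
        return None
    return best


def batch_fragment_hits(
    fragments: Sequence[tuple[int, str]],
    query_seq: str,
    index: KmerIndex,
    params: AlignParams = ANI_FRAGMENT,
    seed_matches: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> list[HSP | None]:
    """Best reference placement for every (global_offset, seq) fragment of a
    query genome.

    Equivalent to calling :func:`best_fragment_hit` per fragment, but the
    seed scan runs once per strand over the whole query and is then sliced
    per fragment, which is what makes fragment-based ANI cheap at genome
    scale.
    """
    per_strand = seed_matches or {
        strand: index.matches(query_seq, strand) for strand in "+-"
    }
    out: list[HSP | None] = []
    for off, frag in fragments:
        best: HSP | None = None
        for strand in "+-":
            qp, sp = per_strand[strand]
            lo, hi = np.searchsorted(qp, [off, off + len(frag) - params.kmer_size + 1])
            hsp = _strand_fragment_hit(
                frag, index, strand, qp[lo:hi] - off, sp[lo:hi], params
            )
            if hsp is not None and (best is None or hsp.raw_score > best.raw_score):
                best = hsp
        if best is not None and best.evalue > params.evalue_cutoff:
            best = None
        out.append(best)
    return out


# ---------------------------------------------------------------------------
# Protein alignment and reciprocal best hits
# ---------------------------------------------------------------------------

_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_CODE = {aa: i for i, aa in enumerate(_AA_ORDER)}

_B62 = substitution_matrices.load("BLOSUM62")
_B62_ALPHABET = _B62.alphabet
_B62_MATRIX = np.array(_B62, dtype=np.int64)
_B62_LUT = np.full(256, _B62_ALPHABET.index("X"), dtype=np.int64)
for _j, _aa in enumerate(_B62_ALPHABET):
    _B62_LUT[ord(_aa)] = _j


def _aa_codes(seq: str) -> np.ndarray:
    """Residues as BLOSUM62 row indices (unknown letters behave like X)."""
    return _B62_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _ungapped_protein_hsp(ca: np.ndarray, cb: np.ndarray) -> tuple[float, int, int, int]:
    """Gap-free Smith-Waterman of two equal-length proteins on the main
    diagonal: maximal-scoring segment of the column-wise BLOSUM62 scores.

    Returns (score, start, end, identities).  For orthologs without indels
    this equals the optimal local alignment; candidates of unequal length
    go through the full affine aligner instead.
    """
    scores = _B62_MATRIX[ca, cb].astype(float)
    prefix = np.concatenate(([0.0], np.cumsum(scores)))
    run_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - run_min
    j = int(np.argmax(gains))
    best = float(gains[j])
    if best <= 0:
        return 0.0, 0, 0, 0
    i = int(np.argmin(prefix[: j + 1]))
    ident = int((ca[i : j + 1] == cb[i : j + 1]).sum())
    return best, i, j + 1, ident


def _make_protein_aligner(params: AlignParams) -> PairwiseAligner:
    aligner = PairwiseAligner(scoring=None)
    aligner.substitution_matrix = substitution_matrices.load(params.protein_matrix)
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    aligner.mode = "local"
    return aligner


def _sanitize_protein(seq: str) -> str:
    # replace rare extended codes by X so the substitution matrix lookup works
    return "".join(c if c in _AA_CODE or c == "X" else "X" for c in seq)


def align_protein_pair(
    a: str,
    b: str,
    params: AlignParams = PROTEIN_SEARCH,
    query_id: str = "a",
    subject_id: str = "b",
    aligner: PairwiseAligner | None = None,
) -> HSP | None:
    """Optimal local alignment of two proteins (BLOSUM62, affine gaps)."""
    aligner = aligner or _make_protein_aligner(params)
    alns = aligner.align(_sanitize_protein(a), _sanitize_protein(b))
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    counts = aln.counts()
    ident = counts.identities
    mism = counts.mismatches
    gaps = counts.gaps
    cols = ident + mism + gaps
    bits = bitscore(aln.score, params)
    ev = evalue(bits, len(a), len(b))
    (qs, qe) = (int(aln.coordinates[0][0]), int(aln.coordinates[0][-1]))
    (ss, se) = (int(aln.coordinates[1][0]), int(aln.coordinates[1][-1]))
    return HSP(
        query_id=query_id,
        subject_id=subject_id,
        q_start=qs,
        q_end=qe,
        s_start=ss,
        s_end=se,
        strand="+",
        length=cols,
        identities=ident,
        mismatches=mism,
        gaps=gaps,
        raw_score=aln.score,
        bitscore=bits,
        evalue=ev,
    )


def _score_candidates(
    prot_a: ProteomeRecord,
    prot_b: ProteomeRecord,
    params: AlignParams,
    profile_a: "ProteomeProfile | None" = None,
    profile_b: "ProteomeProfile | None" = None,
):
    """Align every k-mer-sharing candidate pair of two proteomes.

    Equal-length candidates take the gap-free fast path, others the full
    affine aligner.  Returns ({(i, j): HSP}, profile_a, profile_b).
    """
    if prot_a.count == 0 or prot_b.count == 0:
        raise ValueError("both proteomes must be non-empty")
    profile_a = profile_a or ProteomeProfile(prot_a, params)
    profile_b = profile_b or ProteomeProfile(prot_b, params)
    shared = profile_a.presence @ profile_b.presence.T
    cand_a, cand_b = np.nonzero(shared >= params.min_seed_hits)
    aligner = _make_protein_aligner(params)
    codes_a = profile_a.codes
    codes_b = profile_b.codes
    hsps: dict[tuple[int, int], HSP] = {}
    for i, j in zip(cand_a.tolist(), cand_b.tolist()):
        ida, seqa = prot_a.proteins[i]
        idb, seqb = prot_b.proteins[j]
        if len(seqa) == len(seqb):
            raw, start, end, ident = _ungapped_protein_hsp(codes_a[i], codes_b[j])
            if raw <= 0:
                continue
            cols = end - start
            bits = bitscore(raw, params)
            hsp = HSP(
                query_id=ida,
                subject_id=idb,
                q_start=start,
                q_end=end,
                s_start=start,
                s_end=end,
                strand="+",
                length=cols,
                identities=ident,
                mismatches=cols - ident,
                raw_score=raw,
                bitscore=bits,
                evalue=evalue(bits, len(seqa), len(seqb)),
            )
        else:
            hsp = align_protein_pair(seqa, seqb, params, ida, idb, aligner=aligner)
        if hsp is not None:
            hsps[(i, j)] = hsp
    return hsps, profile_a, profile_b


def qualifying_hit_counts(
    prot_a: ProteomeRecord,
    prot_b: ProteomeRecord,
    params: AlignParams = PROTEIN_SEARCH,
    min_identity: float = 30.0,
    min_coverage: float = 0.70,
    profile_a: "ProteomeProfile | None" = None,
    profile_b: "ProteomeProfile | None" = None,
) -> tuple[int, int]:
    """Per-direction conserved-protein counts: how many proteins of each
    proteome have at least one hit in the other passing the E-value,
    identity and coverage filters (no reciprocity requirement).

    This is the ingredient of the one-directional POCP variant; the default
    POCP path uses the reciprocal-best-hit count instead.
    """
    hsps, _, _ = _score_candidates(
        prot_a, prot_b, params, profile_a, profile_b
    )
    hit_a: set[int] = set()
    hit_b: set[int] = set()
    for (i, j), hsp in hsps.items():
        shorter = min(len(prot_a.proteins[i][1]), len(prot_b.proteins[j][1]))
        if (
            hsp.evalue <= params.evalue_cutoff
            and hsp.pident >= min_identity
            and hsp.length >= min_coverage * shorter
        ):
            hit_a.add(i)
            hit_b.add(j)
    return len(hit_a), len(hit_b)


def _kmer_presence_matrix(prot: ProteomeRecord, k: int) -> np.ndarray:
    """Binary (n_proteins x 20**k) presence matrix of protein k-mers."""
    dim = 20**k
    mat = np.zeros((prot.count, dim), dtype=np.float32)
    for row, (_, seq) in enumerate(prot.proteins):
        codes = np.array([_AA_CODE.get(c, -1) for c in seq], dtype=np.int64)
        if len(codes) < k:
            continue
        idx = np.zeros(len(codes) - k + 1, dtype=np.int64)
        valid = np.ones(len(codes) - k + 1, dtype=bool)
        for j in range(k):
            window = codes[j : j + len(idx)]
            idx = idx * 20 + np.where(window >= 0, window, 0)
            valid &= window >= 0
        mat[row, np.unique(idx[valid])] = 1.0
    return mat


class ProteomeProfile:
    """Cached per-proteome search structures (k-mer presence matrix and
    residue codes), reusable across many pairwise searches."""

    def __init__(self, prot: ProteomeRecord, params: AlignParams = PROTEIN_SEARCH):
        self.record = prot
        self.presence = _kmer_presence_matrix(prot, params.kmer_size)
        self.codes = [_aa_codes(seq) for _, seq in prot.proteins]


def reciprocal_best_hits(
    prot_a: ProteomeRecord,
    prot_b: ProteomeRecord,
    params: AlignParams = PROTEIN_SEARCH,
    min_identity: float = 30.0,
    min_coverage: float = 0.70,
    profile_a: "ProteomeProfile | None" = None,
    profile_b: "ProteomeProfile | None" = None,
) -> list[tuple[str, str, float]]:
    """Bidirectional best-hit protein pairs between two proteomes.

    Candidate pairs are those sharing at least ``params.min_seed_hits``
    k-mers (computed as a presence-matrix product); candidates are aligned
    optimally and a pair is reported iff each member is the other's best
    scoring hit and the alignment passes the E-value, identity and coverage
    filters (coverage relative to the shorter protein).  Each protein
    appears at most once.  Ties between equal-scoring hits are broken by
    input order, so the result is deterministic.
    """
    hsps, _, _ = _score_candidates(prot_a, prot_b, params, profile_a, profile_b)
    best_for_a: dict[int, tuple[float, int]] = {}
    best_for_b: dict[int, tuple[float, int]] = {}
    for (i, j), hsp in sorted(hsps.items()):
        if i not in best_for_a or hsp.raw_score > best_for_a[i][0]:
            best_for_a[i] = (hsp.raw_score, j)
        if j not in best_for_b or hsp.raw_score > best_for_b[j][0]:
            best_for_b[j] = (hsp.raw_score, i)
    pairs: list[tuple[str, str, float]] = []
    for i in sorted(best_for_a):
        j = best_for_a[i][1]
        if best_for_b[j][1] != i:
            continue
        hsp = hsps[(i, j)]
        shorter = min(len(prot_a.proteins[i][1]), len(prot_b.proteins[j][1]))
        if (
            hsp.evalue <= params.evalue_cutoff
            and hsp.pident >= min_identity
            and hsp.length >= min_coverage * shorter
        ):
            pairs.append((hsp.query_id, hsp.subject_id, hsp.pident))
    return pairs


# ---------------------------------------------------------------------------
# Tabular HSP dump (BLAST outfmt-6-like; 1-based inclusive coordinates)
# ---------------------------------------------------------------------------


def hsps_to_tsv(hsps: Sequence[HSP], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "qseqid\tsseqid\tpident\tlength\tmismatch\tgapopen\t"
            "qstart\tqend\tsstart\tsend\tevalue\tbitscore\n"
        )
        for h in hsps:
            if h.strand == "+":
                s1, s2 = h.s_start + 1, h.s_end
            else:
                s1, s2 = h.s_end, h.s_start + 1
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pident:.2f}\t{h.length}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.q_start + 1}\t{h.q_end}\t"
                f"{s1}\t{s2}\t{h.evalue:.2e}\t{h.bitscore:.1f}\n"
            )
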