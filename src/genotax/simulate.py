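"""Synthetic genome/proteome sets with known evolutionary structure.

The generator plants a genus/species taxonomy: an ancestral genome and
proteome evolve down an ultrametric tree whose three depth tiers control the
realized divergence between genome pairs of the same species, the same genus,
and different genera.  Substitution fractions are per-branch realized targets
(not rates needing a saturation correction), so the truth oracle — realized
per-pair divergence, shared-gene bookkeeping — is exact and recovery tests
can be tight.  Proteins are simulated directly rather than translated from
the genome, which keeps amino-acid-level indexes decoupled from gene calling.

Default divergence tiers mirror the index ranges that delimit prokaryotic
taxa: within species ~1% nucleotide divergence (ANI ~99, dDDH well above
70), within genus ~12% nucleotide / 15% amino-acid divergence (ANI ~88,
AAI ~85), between genera ~30% nucleotide / 40% amino-acid divergence
(AAI in the mid-60s, below the 71% genus bound).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
import numpy as np

from .io import GenomeRecord, ProteomeRecord

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)


@dataclass
class SimulationParams:
    """Knobs of the planted-taxonomy generator (all divergences are realized
    substitution-fraction targets between pairs of the named tier)."""

    seed: int = 0
    n_genera: int = 3
    species_per_genus: int = 2
    genomes_per_species: int = 2
    genome_length: int = 100_000
    gc_target: float = 50.0
    within_species_sub: float = 0.01
    within_genus_sub: float = 0.12
    between_genus_sub: float = 0.30
    indel_rate: float = 0.0
    mean_indel_len: int = 3
    n_genes: int = 500
    gene_length_aa: int = 300
    #: fraction of the genus gene set carried by each species
    shared_gene_fraction_within_genus: float = 0.85
    #: fraction of the global gene pool carried by each genus
    genus_gene_fraction: float = 0.90
    protein_sub_within_species: float = 0.01
    protein_sub_within_genus: float = 0.15
    protein_sub_between_genus: float = 0.40

    def __post_init__(self) -> None:
        for name in (
            "within_species_sub",
            "within_genus_sub",
            "between_genus_sub",
            "indel_rate",
            "shared_gene_fraction_within_genus",
            "genus_gene_fraction",
            "protein_sub_within_species",
            "protein_sub_within_genus",
            "protein_sub_between_genus",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (
            self.within_species_sub < self.within_genus_sub < self.between_genus_sub
        ):
            raise ValueError(
                "divergence tiers must satisfy within_species < within_genus "
                "< between_genus"
            )


@dataclass
class SimulationTruth:
    """Ground truth of a simulated clade set (the oracle for recovery tests)."""

    true_tree_newick: str
    genus_partition: dict[str, str]
    species_partition: dict[str, str]
    #: per unordered pair: realized nucleotide substitution fraction
    #: (None when indels make a positional comparison undefined)
    realized_nt_divergence: dict[tuple[str, str], float | None]
    #: per unordered pair: realized amino-acid divergence over shared genes
    realized_aa_divergence: dict[tuple[str, str], float | None]
    gene_sets: dict[str, frozenset[int]]
    #: per genome: substitutions relative to the root ancestor, as
    #: (position, ref_base, alt_base); indel events are recorded separately
    mutation_log: dict[str, list[tuple[int, str, str]]]
    indel_log: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "true_tree_newick": self.true_tree_newick,
            "genus_partition": self.genus_partition,
            "species_partition": self.species_partition,
            "realized_nt_divergence": {
                f"{a}|{b}": v for (a, b), v in self.realized_nt_divergence.items()
            },
            "realized_aa_divergence": {
                f"{a}|{b}": v for (a, b), v in self.realized_aa_divergence.items()
            },
            "gene_sets": {g: sorted(s) for g, s in self.gene_sets.items()},
            "n_substitutions": {g: len(v) for g, v in self.mutation_log.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def truth_index(
    truth: SimulationTruth, pair: tuple[str, str]
) -> tuple[float | None, float | None, float]:
    """(expected_ani, expected_aai, expected_pocp) for a simulated pair,
    computed from the truth bookkeeping alone (no alignment)."""
    a, b = pair
    key = (a, b) if (a, b) in truth.realized_nt_divergence else (b, a)
    nt = truth.realized_nt_divergence[key]
    aa = truth.realized_aa_divergence[key]
    sa, sb = truth.gene_sets[a], truth.gene_sets[b]
    pocp = 2 * len(sa & sb) / (len(sa) + len(sb)) * 100
    return (
        None if nt is None else 100.0 * (1.0 - nt),
        None if aa is None else 100.0 * (1.0 - aa),
        pocp,
    )


# ---------------------------------------------------------------------------
# Elementary generators
# ---------------------------------------------------------------------------


def _ancestor_codes(length: int, gc_target: float, rng: np.random.Generator) -> np.ndarray:
    gc = gc_target / 100.0
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def simulate_ancestor(length: int, gc_target: float, seed: int) -> GenomeRecord:
    """I.i.d. ancestral genome with P(G)+P(C) = gc_target/100, split equally."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    codes = _ancestor_codes(length, gc_target, rng)
    return GenomeRecord(id=f"ancestor_{seed}", contigs=[_decode(codes)])


def _decode(codes: np.ndarray) -> str:
    return _NT[codes].tobytes().decode()


def _encode(seq: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _substitute(
    codes: np.ndarray, fraction: float, rng: np.random.Generator, n_states: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Substitute each site independently with probability ``fraction`` to a
    uniformly chosen different state; returns (new, positions, old_states)."""
    out = codes.copy()
    pos = np.nonzero(rng.random(len(codes)) < fraction)[0]
    old = out[pos].copy()
    out[pos] = (old + rng.integers(1, n_states, size=len(pos))) % n_states
    return out, pos, old


def _apply_indels(
    codes: np.ndarray,
    indel_rate: float,
    mean_len: int,
    rng: np.random.Generator,
    gc_target: float,
) -> tuple[np.ndarray, list[tuple[str, int, int]]]:
    events: list[tuple[str, int, int]] = []
    n_events = rng.poisson(indel_rate * len(codes))
    for _ in range(n_events):
        pos = int(rng.integers(0, len(codes)))
        length = int(rng.geometric(1.0 / mean_len))
        if rng.random() < 0.5 and len(codes) > length:
            codes = np.concatenate([codes[:pos], codes[pos + length :]])
            events.append(("del", pos, length))
        else:
            ins = _ancestor_codes(length, gc_target, rng)
            codes = np.concatenate([codes[:pos], ins, codes[pos:]])
            events.append(("ins", pos, length))
    return codes, events


def evolve(
    genome: GenomeRecord,
    sub_fraction: float,
    indel_rate: float,
    mean_indel_len: int,
    seed: int,
    gc_target: float = 50.0,
) -> tuple[GenomeRecord, dict]:
    """Evolve a (single-contig view of a) genome by substitutions and indels.

    Returns the evolved genome and a log with the substitution events
    (position, ref, alt, in pre-indel coordinates), indel events, and the
    realized substitution fraction.
    """
    if not 0 <= sub_fraction <= 1 or not 0 <= indel_rate <= 1:
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    codes = _encode(genome.sequence)
    mutated, pos, old = _substitute(codes, sub_fraction, rng, 4)
    log = {
        "substitutions": [
            (int(p), _NT[o : o + 1].tobytes().decode(), _NT[mutated[p] : mutated[p] + 1].tobytes().decode())
            for p, o in zip(pos, old)
        ],
        "indels": [],
        "realized_sub_fraction": len(pos) / len(codes) if len(codes) else 0.0,
    }
    mutated, indel_events = _apply_indels(
        mutated, indel_rate, mean_indel_len, rng, gc_target
    )
    log["indels"] = indel_events
    return GenomeRecord(id=f"{genome.id}_evolved", contigs=[_decode(mutated)]), log


# ---------------------------------------------------------------------------
# Planted-taxonomy clade set
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("children", "nt_len", "aa_len", "label")

    def __init__(self, label=None):
        self.children: list[_Node] = []
        self.nt_len = 0.0  # branch above this node, nucleotide sub fraction
        self.aa_len = 0.0  # same branch, amino-acid sub fraction
        self.label = label


def _join_ultrametric(
    nodes: list[_Node],
    nt_heights: tuple[float, float],
    aa_heights: tuple[float, float],
    nt_span: tuple[float, float],
    rng: np.random.Generator,
) -> _Node:
    """Join subtrees (all sitting at the lower height) into one root at the
    upper height, with internal joins at random relative heights in
    ``nt_span`` (the same relative heights apply to the protein clock)."""
    nt_lo, nt_hi = nt_heights
    aa_lo, aa_hi = aa_heights
    if len(nodes) == 1:
        nodes[0].nt_len += nt_hi - nt_lo
        nodes[0].aa_len += aa_hi - aa_lo
        return nodes[0]
    n_join = len(nodes) - 1
    rel = np.sort(rng.uniform(nt_span[0], nt_span[1], size=n_join))
    rel[-1] = 1.0
    # track each subtree's current (relative) height; leaves of this level = 0
    pool = [(node, 0.0) for node in nodes]
    for r in rel:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        (na, ha), (nb, hb) = pool[i], pool[j]
        na.nt_len += (r - ha) * (nt_hi - nt_lo)
        na.aa_len += (r - ha) * (aa_hi - aa_lo)
        nb.nt_len += (r - hb) * (nt_hi - nt_lo)
        nb.aa_len += (r - hb) * (aa_hi - aa_lo)
        parent = _Node()
        parent.children = [na, nb]
        pool = [p for k, p in enumerate(pool) if k not in (i, j)] + [(parent, r)]
    root = pool[0][0]
    return root


def _newick(node: _Node) -> str:
    if not node.children:
        return f"{node.label}:{node.nt_len:.6f}"
    inner = ",".join(_newick(c) for c in node.children)
    return f"({inner}):{node.nt_len:.6f}"


def simulate_clade_set(
    params: SimulationParams,
) -> tuple[dict[str, GenomeRecord], dict[str, ProteomeRecord], SimulationTruth]:
    """Generate a genome/proteome set descending from a planted taxonomy.

    Genome ids are ``g<i>s<j>n<k>`` (genus, species, genome).  The returned
    truth carries the generating tree, both partitions, realized pairwise
    divergences, gene sets and per-genome substitution logs.
    """
    p = params
    rng = np.random.default_rng(p.seed)

    h3_nt, h3_aa = p.within_species_sub / 2, p.protein_sub_within_species / 2
    h2_nt = p.within_genus_sub / 2
    h2_aa = p.protein_sub_within_genus / 2
    h1_nt = p.between_genus_sub / 2
    h1_aa = p.protein_sub_between_genus / 2

    # build the three-tier ultrametric tree bottom-up
    genus_roots: list[_Node] = []
    for gi in range(p.n_genera):
        species_roots: list[_Node] = []
        for si in range(p.species_per_genus):
            leaves = [
                _Node(label=f"g{gi + 1}s{si + 1}n{ni + 1}")
                for ni in range(p.genomes_per_species)
            ]
            species_roots.append(
                _join_ultrametric(leaves, (0.0, h3_nt), (0.0, h3_aa), (0.85, 1.0), rng)
            )
        genus_roots.append(
            _join_ultrametric(
                species_roots, (h3_nt, h2_nt), (h3_aa, h2_aa), (0.6, 1.0), rng
            )
        )
    # deep splits between genera kept close to the root so that every
    # cross-genus pair stays well beyond the within-genus tier
    root = _join_ultrametric(
        genus_roots, (h2_nt, h1_nt), (h2_aa, h1_aa), (0.8, 1.0), rng
    )

    # gene content bookkeeping
    pool = np.arange(p.n_genes)
    genus_sets: list[np.ndarray] = []
    species_sets: dict[tuple[int, int], frozenset[int]] = {}
    m_genus = round(p.genus_gene_fraction * p.n_genes)
    m_species = round(p.shared_gene_fraction_within_genus * m_genus)
    for gi in range(p.n_genera):
        gset = rng.choice(pool, size=m_genus, replace=False)
        genus_sets.append(gset)
        for si in range(p.species_per_genus):
            species_sets[(gi, si)] = frozenset(
                int(x) for x in rng.choice(gset, size=m_species, replace=False)
            )

    # evolve nucleotide genome and protein pool down the tree
    anc_nt = _ancestor_codes(p.genome_length, p.gc_target, rng)
    anc_aa = rng.integers(0, 20, size=p.n_genes * p.gene_length_aa).astype(np.uint8)

    genomes: dict[str, GenomeRecord] = {}
    proteomes: dict[str, ProteomeRecord] = {}
    nt_states: dict[str, np.ndarray] = {}
    aa_states: dict[str, np.ndarray] = {}
    mutation_log: dict[str, list[tuple[int, str, str]]] = {}
    indel_log: dict[str, list[tuple[str, int, int]]] = {}
    genus_partition: dict[str, str] = {}
    species_partition: dict[str, str] = {}
    has_indels = p.indel_rate > 0

    def walk(node: _Node, nt: np.ndarray, aa: np.ndarray, sublog: dict[int, tuple[str, str]], indels):
        nt2, pos, old = _substitute(nt, node.nt_len, rng, 4)
        aa2, _, _ = _substitute(aa, node.aa_len, rng, 20)
        log2 = dict(sublog)
        for pp, oo in zip(pos, old):
            ref = log2.get(int(pp), (_NT[oo : oo + 1].tobytes().decode(),) * 2)[0]
            log2[int(pp)] = (ref, _NT[nt2[pp] : nt2[pp] + 1].tobytes().decode())
        indels2 = list(indels)
        if has_indels:
            nt2, events = _apply_indels(
                nt2, p.indel_rate, p.mean_indel_len, rng, p.gc_target
            )
            indels2.extend(events)
        if not node.children:
            gid = node.label
            nt_states[gid] = nt2
            aa_states[gid] = aa2
            genomes[gid] = GenomeRecord(id=gid, contigs=[_decode(nt2)])
            mutation_log[gid] = sorted(
                (pos_, ref, alt) for pos_, (ref, alt) in log2.items() if ref != alt
            )
            indel_log[gid] = indels2
        else:
            for child in node.children:
                walk(child, nt2, aa2, log2, indels2)

    walk(root, anc_nt, anc_aa, {}, [])

    gene_sets: dict[str, frozenset[int]] = {}
    glen = p.gene_length_aa
    for gi in range(p.n_genera):
        for si in range(p.species_per_genus):
            for ni in range(p.genomes_per_species):
                gid = f"g{gi + 1}s{si + 1}n{ni + 1}"
                genus_partition[gid] = f"g{gi + 1}"
                species_partition[gid] = f"g{gi + 1}s{si + 1}"
                genes = species_sets[(gi, si)]
                gene_sets[gid] = genes
                aa_seq = aa_states[gid]
                proteomes[gid] = ProteomeRecord(
                    genome_id=gid,
                    proteins=[
                        (
                            f"{gid}_p{gene:04d}",
                            _AA[aa_seq[gene * glen : (gene + 1) * glen]].tobytes().decode(),
                        )
                        for gene in sorted(genes)
                    ],
                )

    ids = sorted(genomes)
    realized_nt: dict[tuple[str, str], float | None] = {}
    realized_aa: dict[tuple[str, str], float | None] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if has_indels:
                realized_nt[(a, b)] = None
            else:
                realized_nt[(a, b)] = float(
                    np.mean(nt_states[a] != nt_states[b])
                )
            shared = sorted(gene_sets[a] & gene_sets[b])
            if shared:
                idx = np.concatenate(
                    [np.arange(g * glen, (g + 1) * glen) for g in shared]
                )
                realized_aa[(a, b)] = float(
                    np.mean(aa_states[a][idx] != aa_states[b][idx])
                )
            else:
                realized_aa[(a, b)] = None

    truth = SimulationTruth(
        true_tree_newick=_newick(root).rsplit(":", 1)[0] + ";",
        genus_partition=genus_partition,
        species_partition=species_partition,
        realized_nt_divergence=realized_nt,
        realized_aa_divergence=realized_aa,
        gene_sets=gene_sets,
        mutation_log=mutation_log,
        indel_log=indel_log,
    )
    return genomes, proteomes, truth


def simulate_proteome_pair(
    t1: int,
    t2: int,
    shared: int,
    divergence: float,
    seed: int,
    gene_length_aa: int = 300,
) -> tuple[ProteomeRecord, ProteomeRecord, float]:
    """Two proteomes with exactly ``shared`` orthologous genes (T1, T2 total)
    diverged at the given amino-acid fraction; unshared genes are unrelated.

    Returns (proteome_a, proteome_b, realized_divergence) — the construction
    fixes S, T1 and T2, so the expected POCP is 2S/(T1+T2)*100 exactly.
    """
    if shared > min(t1, t2):
        raise ValueError("shared must not exceed either proteome size")
    rng = np.random.default_rng(seed)
    glen = gene_length_aa
    core = rng.integers(0, 20, size=shared * glen).astype(np.uint8)
    a_extra = rng.integers(0, 20, size=(t1 - shared) * glen).astype(np.uint8)
    b_extra = rng.integers(0, 20, size=(t2 - shared) * glen).astype(np.uint8)
    core_a, _, _ = _substitute(core, divergence / 2, rng, 20)
    core_b, _, _ = _substitute(core, divergence / 2, rng, 20)
    realized = float(np.mean(core_a != core_b))

    def build(gid, core_seq, extra):
        prots = [
            (f"{gid}_core{i:04d}", _AA[core_seq[i * glen : (i + 1) * glen]].tobytes().decode())
            for i in range(shared)
        ]
        n_extra = len(extra) // glen
        prots += [
            (f"{gid}_uniq{i:04d}", _AA[extra[i * glen : (i + 1) * glen]].tobytes().decode())
            for i in range(n_extra)
        ]
        return ProteomeRecord(genome_id=gid, proteins=prots)

    return build("A", core_a, a_extra), build("B", core_b, b_extra), realized


def write_clade_set(
    genomes: dict[str, GenomeRecord],
    proteomes: dict[str, ProteomeRecord],
    truth: SimulationTruth,
    outdir,
) -> None:
    """Write a simulated set as pipeline-ready files: genome and proteome
    FASTAs, a sample sheet, the truth JSON and the true tree Newick."""
    from pathlib import Path

    from .io import (
        SampleSheetEntry,
        StrainMetadata,
        write_genome_fasta,
        write_proteome_fasta,
        write_sample_sheet,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for gid in sorted(genomes):
        gpath = outdir / f"{gid}.fna"
        write_genome_fasta(genomes[gid], gpath)
        ppath = None
        if gid in proteomes:
            ppath = outdir / f"{gid}.faa"
            write_proteome_fasta(proteomes[gid], ppath)
        entries.append(
            SampleSheetEntry(
                id=gid,
                genome_path=gpath,
                proteome_path=ppath,
                metadata=StrainMetadata(name=""),
            )
        )
    write_sample_sheet(entries, outdir / "sample_sheet.tsv")
    truth.to_json(outdir / "truth.json")
    (outdir / "true_tree.nwk").write_text(truth.true_tree_newick + "\n")
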