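"""Synthetic genomes, codon evolution, expression and qPCR data with truth.

Every downstream stage of the pipeline is exercised against data generated
here, with the planted ground truth returned alongside: a multi-chromosome
genome carrying a multigene family defined by a shared ~100-residue domain,
tandem clusters spaced inside the 200-kb window, collinear duplicated
segments whose anchor pairs diverged at known Ks and omega (dN/dS), decoy
genes with no domain (verified by rejection sampling against the domain
profile), FPKM matrices with planted tissue patterns and stress classes,
and Ct tables constructed so 2^-ddCt recovers known fold changes.

The codon-evolution process is Goldman-Yang-like but deliberately matched
to the downstream Nei-Gojobori estimator's assumptions: equal codon
frequencies and no transition/transversion bias, synonymous changes at the
neutral rate and nonsynonymous at omega times that rate, stop-creating
changes forbidden. Under that process the expected synonymous divergence
per synonymous site between the two descendants equals the target Ks, so
parameter recovery is a clean test.

All randomness flows from one seeded generator per call; identical seeds
give byte-identical artifacts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .domain import AMINO_ACIDS, build_profile, encode_protein, window_scores
from .duplication import CODON_AA, SENSE_CODONS, STOP_CODONS, NUCLEOTIDES, SYN_SITES
from .io import (
    CT_COLUMNS, ExpressionMatrix, GeneModel, write_fasta, write_gff3,
    write_expression_table, write_ct_table,
)

# A synthetic ~100-residue consensus standing in for the compact conserved
# domain that defines the family (alpha-crystallin-domain-like in length and
# beta-sandwich-ish composition; the sequence itself is invented).
DEFAULT_DOMAIN_CONSENSUS = (
    "DVKEYPNSYVFMVDMPGLKSGDIKVQVEDDNVLVISGERKREEEKEGVKYLRMERRVGKF"
    "MRKFVLPENAKVDQVKASMENGVLTVTVPKEEVKKPEVKSIQIS"
)

AA_TO_CODONS: dict[str, list[str]] = {}
for _codon in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_AA[_codon], []).append(_codon)

# per-codon single-nucleotide neighbors, split synonymous / nonsynonymous,
# stop codons excluded entirely
CODON_NEIGHBORS: dict[str, tuple[list[str], list[str]]] = {}
for _codon in SENSE_CODONS:
    syn, nonsyn = [], []
    for _pos in range(3):
        for _nt in NUCLEOTIDES:
            if _nt == _codon[_pos]:
                continue
            _n = _codon[:_pos] + _nt + _codon[_pos + 1 :]
            if _n in STOP_CODONS:
                continue
            (syn if CODON_AA[_n] == CODON_AA[_codon] else nonsyn).append(_n)
    CODON_NEIGHBORS[_codon] = (syn, nonsyn)

_NT_ARRAY = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Sequence-level helpers
# ---------------------------------------------------------------------------

def mutate_protein(sequence: str, substitution_prob: float, rng: np.random.Generator) -> str:
    out = []
    for ch in sequence:
        if rng.random() < substitution_prob:
            choices = [a for a in AMINO_ACIDS if a != ch]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(ch)
    return "".join(out)


def random_protein(length: int, composition: np.ndarray, rng: np.random.Generator) -> str:
    idx = rng.choice(20, size=length, p=composition)
    return "".join(AMINO_ACIDS[i] for i in idx)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous codon per residue (X falls back to GGN glycine)."""
    codons = []
    for aa in protein:
        options = AA_TO_CODONS.get(aa, AA_TO_CODONS["G"])
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def _evolve_branch(
    codons: list[str], t: float, omega: float, rng: np.random.Generator
) -> tuple[list[str], int, int]:
    """Evolve codons for time t (Gillespie per codon); returns realized counts."""
    syn_events = nonsyn_events = 0
    out = []
    for codon in codons:
        remaining = t
        while True:
            syn, nonsyn = CODON_NEIGHBORS[codon]
            rate = len(syn) + omega * len(nonsyn)
            if rate <= 0:
                break
            wait = rng.exponential(1.0 / rate)
            if wait > remaining:
                break
            remaining -= wait
            u = rng.random() * rate
            if u < len(syn):
                codon = syn[int(u)]
                syn_events += 1
            else:
                k = int((u - len(syn)) / omega)
                codon = nonsyn[min(k, len(nonsyn) - 1)]
                nonsyn_events += 1
        out.append(codon)
    return out, syn_events, nonsyn_events


def evolve_codon_pair(
    ancestor_cds: str,
    target_Ks: float,
    omega: float,
    seed: int | np.random.Generator = 0,
) -> tuple[str, str, dict[str, int]]:
    """Two descendants of an ancestral CDS at a target synonymous divergence.

    Each branch runs the codon substitution process for time t = Ks/6: a
    codon's synonymous substitution rate is (number of synonymous
    neighbors) and Nei-Gojobori counts ~1/3 of each position as a
    synonymous site, so expected synonymous substitutions per synonymous
    site per branch is 3t = Ks/2, i.e. Ks between the two descendants.
    Stop-creating changes never occur. Returns the realized substitution
    counts summed over both branches.
    """
    if target_Ks < 0:
        raise ValueError("target_Ks must be >= 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if len(ancestor_cds) % 3 != 0:
        raise ValueError("ancestor CDS length must be a multiple of 3")
    ancestor_cds = ancestor_cds.upper()
    codons = [ancestor_cds[i : i + 3] for i in range(0, len(ancestor_cds), 3)]
    for c in codons:
        if c in STOP_CODONS:
            raise ValueError("ancestor CDS contains a stop codon")
        if c not in CODON_AA:
            raise ValueError(f"ancestor CDS contains non-sense codon {c!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # branch time such that expected synonymous events per branch equal
    # (Ks/2) * (NG synonymous sites): the synonymous event rate of codon c
    # is its synonymous-neighbor count, while NG counts syn/valid sites, and
    # the two differ where stop-codon neighbors are excluded
    total_sites = sum(SYN_SITES[c] for c in codons)
    total_rate = sum(len(CODON_NEIGHBORS[c][0]) for c in codons)
    t = 0.5 * target_Ks * total_sites / total_rate if total_rate > 0 else 0.0
    codons_a, syn_a, nonsyn_a = _evolve_branch(codons, t, omega, rng)
    codons_b, syn_b, nonsyn_b = _evolve_branch(codons, t, omega, rng)
    counts = {
        "synonymous": syn_a + syn_b,
        "nonsynonymous": nonsyn_a + nonsyn_b,
    }
    return "".join(codons_a), "".join(codons_b), counts


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

@dataclass
class TandemSpec:
    chromosome: int  # 0-based chromosome index
    n_genes: int = 3
    spacing: int = 60_000  # start-to-start distance, < tandem window


@dataclass
class CollinearSpec:
    chrom_a: int
    chrom_b: int
    n_anchors: int = 4
    n_intervening: int = 2  # decoy genes between consecutive anchors, <= gap


@dataclass
class GenomeSimParams:
    seed: int = 0
    n_chromosomes: int = 3
    n_family_genes: int = 14
    n_decoys: int = 30
    domain_consensus: str = DEFAULT_DOMAIN_CONSENSUS
    substitution_prob: float = 0.10  # per-site domain divergence per lineage
    tandem_specs: list[TandemSpec] = field(
        default_factory=lambda: [TandemSpec(0, 3, 60_000), TandemSpec(1, 2, 120_000)]
    )
    collinear_specs: list[CollinearSpec] = field(
        default_factory=lambda: [CollinearSpec(0, 2, 3, 2)]
    )
    pair_ks_range: tuple[float, float] = (0.1, 0.4)
    pair_omega: float = 0.25
    singleton_ks: float = 0.06
    intron_fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    flank_range: tuple[int, int] = (25, 60)
    tandem_window: int = 200_000
    chromosome_length: int | None = None  # feasibility bound, optional


@dataclass
class SyntheticTruth:
    family_gene_ids: list[str] = field(default_factory=list)
    decoy_gene_ids: list[str] = field(default_factory=list)
    domain_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    lineages: dict[str, str] = field(default_factory=dict)  # gene -> subfamily label
    true_tree: str = ""
    tandem_clusters: list[dict] = field(default_factory=list)
    collinear_blocks: list[dict] = field(default_factory=list)
    pair_params: dict[str, tuple[float, float]] = field(default_factory=dict)  # "a|b" -> (Ks, omega)
    intron_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)


@dataclass
class SyntheticGenome:
    chromosomes: dict[str, str]
    genes: list[GeneModel]
    proteins: list[tuple[str, str]]
    cds: dict[str, str]
    truth: SyntheticTruth

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(sorted(self.chromosomes.items()), out / "genome.fasta")
        write_gff3(self.genes, out / "genes.gff3")
        write_fasta(self.proteins, out / "proteins.fasta")
        write_fasta(sorted(self.cds.items()), out / "cds.fasta")
        self.truth.to_json(out / "truth.json")


def _translate_cds(cds: str) -> str:
    aas = []
    for i in range(0, len(cds) - 3, 3):  # drop trailing stop
        aas.append(CODON_AA[cds[i : i + 3]])
    return "".join(aas)


def _composition(proteins: list[str]) -> np.ndarray:
    counts = np.ones(20)
    for p in proteins:
        enc = encode_protein(p)
        counts += np.bincount(enc[enc < 20], minlength=20)
    return counts / counts.sum()


def generate_family_genome(params: GenomeSimParams) -> SyntheticGenome:
    """Genome + gene models + proteins + CDS + planted truth.

    Family proteins each carry exactly one diverged copy of the domain
    consensus; decoys carry none (rejection-sampled against the profile).
    The layout realizes the requested tandem clusters (consecutive starts
    within their spacing) and collinear blocks (anchor pairs in preserved
    order with the requested number of intervening decoys); non-cluster
    family genes are always separated by more than the tandem window.
    """
    rng = np.random.default_rng(params.seed)
    consensus = params.domain_consensus
    truth = SyntheticTruth()

    demand = sum(s.n_genes for s in params.tandem_specs) + sum(
        2 * s.n_anchors for s in params.collinear_specs
    )
    if demand > params.n_family_genes:
        raise ValueError(
            f"layout needs {demand} family genes but n_family_genes={params.n_family_genes}"
        )
    for spec in params.tandem_specs + params.collinear_specs:
        chroms = [spec.chromosome] if isinstance(spec, TandemSpec) else [spec.chrom_a, spec.chrom_b]
        for c in chroms:
            if c >= params.n_chromosomes:
                raise ValueError(f"spec references chromosome {c} of {params.n_chromosomes}")
    if any(s.spacing >= params.tandem_window for s in params.tandem_specs):
        raise ValueError("tandem spacing must be below the tandem window")

    # ---- family sequences, lineage by lineage -------------------------------
    fam_counter = 0
    background_comp = np.full(20, 1 / 20)

    def new_lineage_ancestor() -> tuple[str, str, tuple[int, int]]:
        """(ancestor protein, ancestor CDS, domain interval 1-based)."""
        domain = mutate_protein(consensus, params.substitution_prob, rng)
        n_len = int(rng.integers(*params.flank_range))
        c_len = int(rng.integers(*params.flank_range))
        nflank = random_protein(n_len, background_comp, rng)
        cflank = random_protein(c_len, background_comp, rng)
        protein = nflank + domain + cflank
        cds = back_translate(protein, rng) + "TAA"
        return protein, cds, (n_len + 1, n_len + len(consensus))

    def next_fam_id() -> str:
        nonlocal fam_counter
        fam_counter += 1
        return f"fam{fam_counter:03d}"

    family: dict[str, dict] = {}  # gene id -> {cds, protein, interval, lineage}

    def add_member(cds: str, interval: tuple[int, int], lineage: str) -> str:
        gid = next_fam_id()
        family[gid] = {
            "cds": cds, "protein": _translate_cds(cds),
            "interval": interval, "lineage": lineage,
        }
        truth.lineages[gid] = lineage
        truth.domain_intervals[gid] = interval
        return gid

    # tandem clusters: members branch-evolved from one lineage ancestor
    tandem_members: list[tuple[int, list[str], int]] = []  # (chrom, members, spacing)
    for t_idx, spec in enumerate(params.tandem_specs):
        _prot, anc_cds, interval = new_lineage_ancestor()
        lineage = f"T{t_idx + 1}"
        members = []
        for _ in range(spec.n_genes):
            ks = float(rng.uniform(*params.pair_ks_range))
            codons = [anc_cds[i : i + 3] for i in range(0, len(anc_cds) - 3, 3)]
            evolved, _s, _n = _evolve_branch(codons, ks / 6.0, params.pair_omega, rng)
            members.append(add_member("".join(evolved) + "TAA", interval, lineage))
        tandem_members.append((spec.chromosome, members, spec.spacing))
        truth.tandem_clusters.append({"chromosome": f"chr{spec.chromosome + 1}", "members": members})

    # collinear blocks: each anchor pair is its own lineage
    collinear_layouts: list[tuple[CollinearSpec, list[tuple[str, str]]]] = []
    for b_idx, spec in enumerate(params.collinear_specs):
        anchors = []
        for a_idx in range(spec.n_anchors):
            _prot, anc_cds, interval = new_lineage_ancestor()
            lineage = f"B{b_idx + 1}A{a_idx + 1}"
            ks = float(rng.uniform(*params.pair_ks_range))
            cds_a, cds_b, _counts = evolve_codon_pair(anc_cds[:-3], ks, params.pair_omega, rng)
            ga = add_member(cds_a + "TAA", interval, lineage)
            gb = add_member(cds_b + "TAA", interval, lineage)
            anchors.append((ga, gb))
            truth.pair_params[f"{ga}|{gb}"] = (ks, params.pair_omega)
        collinear_layouts.append((spec, anchors))
        truth.collinear_blocks.append({
            "chrom_a": f"chr{spec.chrom_a + 1}", "chrom_b": f"chr{spec.chrom_b + 1}",
            "anchors": anchors,
        })

    # singletons, grouped into small lineages of up to 3 for subfamily tests
    singles: list[str] = []
    n_singles = params.n_family_genes - demand
    s_idx = 0
    while len(singles) < n_singles:
        s_idx += 1
        _prot, anc_cds, interval = new_lineage_ancestor()
        lineage = f"S{s_idx}"
        group = min(3, n_singles - len(singles))
        for _ in range(group):
            codons = [anc_cds[i : i + 3] for i in range(0, len(anc_cds) - 3, 3)]
            evolved, _s, _n = _evolve_branch(codons, params.singleton_ks / 6.0,
                                             params.pair_omega, rng)
            singles.append(add_member("".join(evolved) + "TAA", interval, lineage))

    truth.family_gene_ids = sorted(family)
    lineage_groups: dict[str, list[str]] = {}
    for gid in truth.family_gene_ids:
        lineage_groups.setdefault(truth.lineages[gid], []).append(gid)
    if lineage_groups:
        parts = []
        for lin in sorted(lineage_groups):
            members = lineage_groups[lin]
            parts.append("(" + ",".join(members) + ")" if len(members) > 1 else members[0])
        truth.true_tree = "(" + ",".join(parts) + ");"

    # ---- decoys: family-like composition, no domain -------------------------
    family_proteins = [family[g]["protein"] for g in truth.family_gene_ids]
    decoy_comp = _composition(family_proteins) if family_proteins else background_comp
    seed_rows = [consensus] + [mutate_protein(consensus, params.substitution_prob, rng)
                               for _ in range(4)]
    reject_profile = build_profile(seed_rows)
    if family_proteins:
        fam_scores = [
            float(window_scores(reject_profile, encode_protein(p)).max())
            for p in family_proteins
        ]
        reject_threshold = 0.5 * min(fam_scores)
    else:
        self_score = float(window_scores(reject_profile, encode_protein(consensus)).max())
        reject_threshold = 0.5 * self_score

    decoys: dict[str, str] = {}
    mean_len = int(np.mean([len(p) for p in family_proteins])) if family_proteins else 180
    for d in range(params.n_decoys):
        for _attempt in range(200):
            length = int(rng.integers(max(mean_len - 40, 60), mean_len + 40))
            candidate = random_protein(length, decoy_comp, rng)
            scores = window_scores(reject_profile, encode_protein(candidate))
            if scores.size == 0 or scores.max() < reject_threshold:
                break
        else:
            raise RuntimeError("could not sample a domain-free decoy in 200 attempts")
        decoys[f"dec{d + 1:03d}"] = candidate
    truth.decoy_gene_ids = sorted(decoys)
    decoy_cds = {gid: back_translate(p, rng) + "TAA" for gid, p in decoys.items()}

    # ---- chromosome layout ---------------------------------------------------
    # features are placed left to right; between features the family-gene
    # start spacing always exceeds the tandem window
    far = params.tandem_window
    chrom_features: dict[int, list[list[tuple[str, int]]]] = {
        c: [] for c in range(params.n_chromosomes)
    }

    for chrom, members, spacing in tandem_members:
        chrom_features[chrom].append([(gid, i * spacing) for i, gid in enumerate(members)])

    decoy_pool = sorted(decoys)
    pool_pos = 0

    def take_decoy() -> str:
        nonlocal pool_pos
        if pool_pos >= len(decoy_pool):
            raise ValueError("not enough decoys for the requested intervening genes")
        gid = decoy_pool[pool_pos]
        pool_pos += 1
        return gid

    for spec, anchors in collinear_layouts:
        anchor_gap = far + 20_000
        for side, chrom in ((0, spec.chrom_a), (1, spec.chrom_b)):
            feature = []
            offset = 0
            for a_idx, pair in enumerate(anchors):
                feature.append((pair[side], offset))
                if a_idx < len(anchors) - 1:
                    step = anchor_gap // (spec.n_intervening + 1)
                    for k in range(spec.n_intervening):
                        feature.append((take_decoy(), offset + (k + 1) * step))
                    offset += anchor_gap
            chrom_features[chrom].append(feature)

    leftovers = singles + decoy_pool[pool_pos:]
    for k, gid in enumerate(leftovers):
        chrom_features[k % params.n_chromosomes].append([(gid, 0)])

    all_cds = {**{g: family[g]["cds"] for g in family}, **decoy_cds}

    # ---- gene models + genome sequence --------------------------------------
    genes: list[GeneModel] = []
    chromosomes: dict[str, str] = {}
    for chrom_idx in range(params.n_chromosomes):
        chrom_name = f"chr{chrom_idx + 1}"
        placements: list[tuple[str, int]] = []
        cursor = 10_000
        for feature in chrom_features[chrom_idx]:
            for gid, offset in feature:
                placements.append((gid, cursor + offset))
            span = max(off for _g, off in feature)
            cursor += span + far + int(rng.integers(20_000, 80_000))
        length = cursor + 10_000
        if params.chromosome_length is not None and length > params.chromosome_length:
            raise ValueError(
                f"layout infeasible: {chrom_name} needs {length} bp "
                f"> chromosome_length {params.chromosome_length}"
            )
        seq = rng.integers(0, 4, size=length, dtype=np.uint8)
        for gid, start in sorted(placements, key=lambda x: x[1]):
            cds = all_cds[gid]
            model, exon_seq = _make_gene_model(gid, chrom_name, start, cds, rng,
                                               params.intron_fractions)
            genes.append(model)
            truth.intron_counts[gid] = model.intron_count
            pos = 0
            for a, b in model.exons:
                chunk = exon_seq[pos : pos + (b - a + 1)]
                seq[a - 1 : b] = np.array([("ACGT".index(ch)) for ch in chunk], dtype=np.uint8)
                pos += b - a + 1
        chromosomes[chrom_name] = "".join("ACGT"[i] for i in seq)

    genes.sort(key=lambda g: (g.chromosome, g.start))
    proteins = [(gid, family[gid]["protein"]) for gid in truth.family_gene_ids]
    proteins += [(gid, decoys[gid]) for gid in truth.decoy_gene_ids]
    return SyntheticGenome(
        chromosomes=chromosomes, genes=genes, proteins=proteins,
        cds=dict(sorted(all_cds.items())), truth=truth,
    )


def _make_gene_model(
    gid: str,
    chrom: str,
    start: int,
    cds: str,
    rng: np.random.Generator,
    intron_fractions: tuple[float, float, float],
) -> tuple[GeneModel, str]:
    """Split a CDS into exons with random introns; returns the model and the
    genomic (forward-strand) exon sequence concatenation."""
    u = rng.random()
    if u < intron_fractions[0]:
        n_introns = 0
    elif u < intron_fractions[0] + intron_fractions[1]:
        n_introns = 1
    else:
        n_introns = int(rng.integers(2, 4))
    n_introns = min(n_introns, len(cds) // 60 - 1) if len(cds) >= 120 else 0
    n_introns = max(n_introns, 0)

    strand = "+" if rng.random() < 0.5 else "-"
    genomic_cds = cds
    if strand == "-":
        complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
        genomic_cds = "".join(complement[ch] for ch in reversed(cds))

    cuts = sorted(rng.choice(np.arange(30, len(cds) - 30), size=n_introns, replace=False)) \
        if n_introns else []
    pieces = []
    prev = 0
    for cut in cuts:
        pieces.append(genomic_cds[prev:cut])
        prev = int(cut)
    pieces.append(genomic_cds[prev:])

    exons = []
    pos = start
    for k, piece in enumerate(pieces):
        exons.append((pos, pos + len(piece) - 1))
        pos += len(piece)
        if k < len(pieces) - 1:
            pos += int(rng.integers(80, 300))  # intron
    end = exons[-1][1]
    model = GeneModel(
        gene_id=gid, chromosome=chrom, start=start, end=end,
        strand=strand, exons=exons, cds_sequence=cds,
    )
    return model, genomic_cds


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def generate_expression_matrix(
    gene_ids: list[str],
    tissues: list[str],
    stresses: list[str],
    tissue_patterns: dict[str, str],
    stress_classes: dict[str, dict[str, str]],
    patterns: dict[str, dict[str, float]] | None = None,
    silent_genes: set[str] | frozenset = frozenset(),
    noise: float = 0.0,
    margin: float = 1.5,
    fold_up: float = 2.0,
    fold_down: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, dict]:
    """FPKM matrix with planted tissue patterns and stress classes.

    Conditions are the tissues plus a control/treatment column pair per
    stress. "up" genes get a treatment/control ratio above fold_up*margin,
    "down" below fold_down/margin, "unchanged" exactly 1 before noise, so
    the calling rules recover the planted labels unambiguously at the
    stated noise. Silent genes stay below FPKM 1 everywhere. Noise is
    multiplicative log-normal with the given log-scale sd.
    """
    if margin <= 1.0:
        raise ValueError("margin must exceed 1")
    if noise > 0 and math.log(margin) < 3.0 * math.sqrt(2.0) * noise:
        raise ValueError(
            f"margin {margin} incompatible with noise level {noise}: "
            f"calls would be ambiguous"
        )
    rng = np.random.default_rng(seed)
    labels = sorted({tissue_patterns[g] for g in gene_ids if g not in silent_genes})
    if patterns is None:
        patterns = {}
        for label in labels:
            patterns[label] = {
                t: float(rng.choice([0.2, 1.0, 8.0])) for t in tissues
            }
            # guarantee at least one clearly expressed tissue per pattern
            patterns[label][tissues[int(rng.integers(len(tissues)))]] = 8.0

    conditions = list(tissues)
    for s in stresses:
        conditions += [f"{s}_control", f"{s}_treatment"]

    def jitter() -> float:
        return float(np.exp(rng.normal(0.0, noise))) if noise > 0 else 1.0

    values = np.zeros((len(gene_ids), len(conditions)))
    truth = {"expressed_any": {}, "tissue_pattern": {}, "stress_class": {}}
    for i, gid in enumerate(gene_ids):
        if gid in silent_genes:
            row = rng.uniform(0.0, 0.8, size=len(conditions))
            for s_idx, s in enumerate(stresses):
                c_col = conditions.index(f"{s}_control")
                row[c_col + 1] = row[c_col]  # unchanged exactly
            values[i] = row
            truth["expressed_any"][gid] = False
            truth["tissue_pattern"][gid] = "silent"
            truth["stress_class"][gid] = {s: "unchanged" for s in stresses}
            continue
        base = float(rng.lognormal(math.log(12.0), 0.4))
        pattern = patterns[tissue_patterns[gid]]
        for j, t in enumerate(tissues):
            values[i, j] = base * pattern[t] * jitter()
        truth["tissue_pattern"][gid] = tissue_patterns[gid]
        truth["stress_class"][gid] = {}
        for s in stresses:
            label = stress_classes.get(gid, {}).get(s, "unchanged")
            control = base * jitter()
            if label == "up":
                ratio = float(rng.uniform(fold_up * margin, fold_up * margin * 2))
            elif label == "down":
                ratio = float(rng.uniform(fold_down / (margin * 2), fold_down / margin))
            else:
                ratio = 1.0
            treatment = control * ratio * jitter()
            c_col = conditions.index(f"{s}_control")
            values[i, c_col] = control
            values[i, c_col + 1] = treatment
            truth["stress_class"][gid][s] = label
        truth["expressed_any"][gid] = bool((values[i] > 1.0).any())
    matrix = ExpressionMatrix(list(gene_ids), conditions, values)
    return matrix, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def generate_ct_table(
    genes: list[str],
    treatments: list[str],
    true_fold_changes: dict[tuple[str, str], float],
    reference_gene: str,
    seed: int = 0,
    calibrator: str = "control",
    n_replicates: int = 3,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Long-format Ct table whose 2^-ddCt recovers the planted fold changes.

    With ``noise_sd`` 0 the recovery is exact: the treatment dCt is the
    calibrator dCt minus log2(fold change). Gaussian noise (sd in Ct units)
    is added per measurement otherwise.
    """
    for key, fold in true_fold_changes.items():
        if fold <= 0:
            raise ValueError(f"fold change for {key} must be > 0, got {fold}")
    rng = np.random.default_rng(seed)
    ref_ct = 15.0
    rows = []
    conditions = [calibrator] + list(treatments)
    base_dct = {g: 5.0 + 0.5 * k for k, g in enumerate(genes)}
    for condition in conditions:
        for rep in range(1, n_replicates + 1):
            noise = lambda: float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
            rows.append({"gene": reference_gene, "condition": condition,
                         "replicate": rep, "Ct": ref_ct + noise()})
            for g in genes:
                dct = base_dct[g]
                if condition != calibrator:
                    fold = true_fold_changes.get((g, condition), 1.0)
                    dct = dct - math.log2(fold)
                rows.append({"gene": g, "condition": condition,
                             "replicate": rep, "Ct": ref_ct + dct + noise()})
    return pd.DataFrame(rows, columns=CT_COLUMNS)
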