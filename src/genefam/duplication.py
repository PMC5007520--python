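"""Duplication detection, Ka/Ks estimation, selection classing, and dating.

Tandem duplication follows the positional rule of the source analysis: a
chromosomal region of 200 kb containing two or more family genes is one
tandem event; runs are closed transitively, so the clusters are exactly the
connected components of the "within 200 kb" pair graph. Segmental
(collinear) duplication is detected by chaining protein-similarity anchors
that advance in gene order on both chromosomes with at most ``gap``
intervening non-anchor genes.

Ka/Ks uses the Nei-Gojobori (1986) method: synonymous/nonsynonymous site
counts by single-nucleotide-neighbor enumeration under the standard code
(stop-codon neighbors excluded from the denominators), observed differences
averaged over all minimal substitution pathways (pathways through stops
discarded), and Jukes-Cantor correction d = -3/4 ln(1 - 4p/3). Duplication
dates follow T = Ks / (2 r) with the neutral rate r = 2.6e-9
substitutions/site/year, reported in million years (Mya).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .calibration import EvalueCalibration
from .config import PipelineConfig, DEFAULT_CONFIG
from .io import GeneModel, ProteinRecord, log_filter

logger = logging.getLogger("genefam")

NUCLEOTIDES = "ACGT"
CODON_AA: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
SENSE_CODONS = sorted(CODON_AA)


# ---------------------------------------------------------------------------
# Nei-Gojobori
# ---------------------------------------------------------------------------

def _codon_site_counts() -> dict[str, float]:
    """Synonymous site count per sense codon (N = 3 - S where defined)."""
    out = {}
    for codon in SENSE_CODONS:
        s = 0.0
        for pos in range(3):
            syn = 0
            valid = 0
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                neighbor = codon[:pos] + nt + codon[pos + 1 :]
                if neighbor in STOP_CODONS:
                    continue
                valid += 1
                if CODON_AA[neighbor] == CODON_AA[codon]:
                    syn += 1
            if valid:
                s += syn / valid
        out[codon] = s
    return out


SYN_SITES = _codon_site_counts()


def _codon_valid_positions(codon: str) -> int:
    """Positions of a codon with at least one non-stop neighbor (site count)."""
    count = 0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                neighbor = codon[:pos] + nt + codon[pos + 1 :]
                if neighbor not in STOP_CODONS:
                    count += 1
                    break
    return count


TOTAL_SITES = {codon: float(_codon_valid_positions(codon)) for codon in SENSE_CODONS}


def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over minimal pathways.

    Pathways passing through a stop codon are discarded; returns NaNs when
    every pathway is blocked.
    """
    diff_positions = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diff_positions:
        return 0.0, 0.0
    syn_totals = []
    nonsyn_totals = []
    for order in itertools.permutations(diff_positions):
        current = codon_a
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_AA[nxt] == CODON_AA[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if not blocked:
            syn_totals.append(syn)
            nonsyn_totals.append(nonsyn)
    if not syn_totals:
        return math.nan, math.nan
    return float(np.mean(syn_totals)), float(np.mean(nonsyn_totals))


def jukes_cantor(p: float) -> float:
    """JC-corrected distance -3/4 ln(1 - 4p/3); NaN at/beyond saturation."""
    if p < 0:
        raise ValueError("proportion of differences cannot be negative")
    if p >= 0.75:
        return math.nan
    if p == 0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class KaKsResult:
    """Site and difference counts with the corrected rates."""

    S: float  # synonymous sites (averaged over the two sequences)
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences
    pS: float
    pN: float
    Ks: float  # NaN when the JC correction is undefined
    Ka: float
    n_codons: int

    @property
    def valid(self) -> bool:
        return not (math.isnan(self.Ks) or math.isnan(self.Ka))


def _split_codons(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def nei_gojobori(codon_alignment: tuple[str, str]) -> KaKsResult:
    """Nei-Gojobori Ka and Ks from a gapped pairwise codon alignment.

    Codon columns containing a gap or ambiguity are skipped; columns
    containing a stop codon are skipped with a warning.
    """
    seq_a, seq_b = (s.upper() for s in codon_alignment)
    if len(seq_a) != len(seq_b) or len(seq_a) % 3 != 0:
        raise ValueError("codon alignment rows must be equal length multiples of 3")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for ca, cb in zip(_split_codons(seq_a), _split_codons(seq_b)):
        if any(ch not in NUCLEOTIDES for ch in ca + cb):
            continue  # gap or ambiguous codon column
        if ca in STOP_CODONS or cb in STOP_CODONS:
            logger.warning("stop codon column (%s/%s) skipped", ca, cb)
            continue
        sd, nd = _pathway_differences(ca, cb)
        if math.isnan(sd):
            logger.warning("all pathways between %s and %s blocked; column skipped", ca, cb)
            continue
        S += 0.5 * (SYN_SITES[ca] + SYN_SITES[cb])
        N += 0.5 * ((TOTAL_SITES[ca] - SYN_SITES[ca]) + (TOTAL_SITES[cb] - SYN_SITES[cb]))
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codon columns in alignment")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS) if pS < 0.75 else math.nan
    Ka = jukes_cantor(pN) if pN < 0.75 else math.nan
    if math.isnan(Ks) or math.isnan(Ka):
        logger.warning("Ka/Ks correction undefined (pS=%.3f, pN=%.3f); pair flagged", pS, pN)
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka, n_codons=n_codons)


def align_codons(protein_alignment: tuple[str, str], cds_a: str, cds_b: str) -> tuple[str, str]:
    """Back-translate a pairwise protein alignment onto the two CDS.

    Each protein column maps to its codon triplet or to a 3-base gap; the
    reading frame is preserved. Trailing stop codons on the CDS are allowed
    and dropped.
    """
    row_a, row_b = protein_alignment
    out = []
    for row, cds in ((row_a, cds_a.upper()), (row_b, cds_b.upper())):
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        ungapped = row.replace("-", "")
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"CDS length {len(cds)} does not match protein length {len(ungapped)} x 3"
            )
        codons = _split_codons(cds)
        for i, codon in enumerate(codons):
            aa = CODON_AA.get(codon)
            if aa is not None and aa != ungapped[i] and ungapped[i] != "X":
                raise ValueError(
                    f"CDS codon {codon} at position {i + 1} translates to {aa}, "
                    f"protein says {ungapped[i]}"
                )
        aligned = []
        k = 0
        for ch in row:
            if ch == "-":
                aligned.append("---")
            else:
                aligned.append(codons[k])
                k += 1
        out.append("".join(aligned))
    return out[0], out[1]


def classify_selection(Ka: float, Ks: float, tol: float = 1e-9) -> str:
    """Selection regime from the Ka/Ks ratio.

    ratio > 1 -> positive, = 1 (within tol) -> neutral, < 1 -> purifying;
    Ks = 0 (or an undefined estimate) -> undefined.
    """
    if math.isnan(Ka) or math.isnan(Ks):
        return "undefined"
    if Ka < 0 or Ks < 0:
        raise ValueError("Ka and Ks must be non-negative")
    if Ks == 0:
        return "undefined"
    ratio = Ka / Ks
    if abs(ratio - 1.0) <= tol:
        return "neutral"
    return "positive" if ratio > 1.0 else "purifying"


def date_duplication(Ks: float, r: float = 2.6e-9) -> float:
    """Duplication date T = Ks / (2 r), in million years (Mya)."""
    if r <= 0:
        raise ValueError("neutral rate r must be > 0")
    if Ks < 0:
        raise ValueError("Ks must be >= 0")
    return Ks / (2.0 * r) / 1e6


@dataclass
class ParalogPair:
    gene_a: str
    gene_b: str
    Ka: float
    Ks: float
    ratio: float  # NaN when Ks == 0 or an estimate is undefined
    selection_class: str
    T_mya: float  # NaN when excluded from dating
    source: str = "similarity"  # similarity | block_anchor


def analyze_pair(
    gene_a: str,
    gene_b: str,
    protein_a: str,
    protein_b: str,
    cds_a: str,
    cds_b: str,
    r: float = 2.6e-9,
    source: str = "similarity",
) -> ParalogPair:
    """Full Ka/Ks/selection/dating analysis of one duplicated gene pair."""
    from .phylo import align_pair  # local import to avoid a module cycle

    row_a, row_b, _score = align_pair(protein_a, protein_b)
    codon_aln = align_codons((row_a, row_b), cds_a, cds_b)
    res = nei_gojobori(codon_aln)
    ratio = res.Ka / res.Ks if res.valid and res.Ks > 0 else math.nan
    t_mya = date_duplication(res.Ks, r) if res.valid else math.nan
    return ParalogPair(
        gene_a=gene_a, gene_b=gene_b, Ka=res.Ka, Ks=res.Ks, ratio=ratio,
        selection_class=classify_selection(res.Ka, res.Ks),
        T_mya=t_mya, source=source,
    )


# ---------------------------------------------------------------------------
# All-vs-all protein similarity
# ---------------------------------------------------------------------------

@dataclass
class SimilarityHit:
    query_id: str
    subject_id: str
    query_span: tuple[int, int]  # 1-based inclusive on the query
    subject_span: tuple[int, int]
    score: float
    evalue: float
    log10_evalue: float
    coverage_of_longer: float


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "local"
    return aligner


def _local_hit(aligner, a: str, b: str):
    alignment = next(iter(aligner.align(a, b)))
    qa = alignment.aligned[0]
    qb = alignment.aligned[1]
    qspan = (int(qa[0][0]) + 1, int(qa[-1][1]))
    sspan = (int(qb[0][0]) + 1, int(qb[-1][1]))
    return float(alignment.score), qspan, sspan


def all_vs_all_similarity(
    proteins: list[ProteinRecord],
    config: PipelineConfig = DEFAULT_CONFIG,
    n_decoys: int = 500,
    seed: int = 0,
) -> list[SimilarityHit]:
    """Retained all-vs-all local-alignment hits between family proteins.

    Smith-Waterman with affine gaps per unordered pair; e-values calibrated
    on shuffled decoy pairs (Gumbel tail). A hit is retained when (i) its
    e-value beats the 1e-20-equivalent gate, (ii) it lies within
    ``best_hit_ratio`` of the query's best non-self hit, and (iii) the
    alignment covers at least half of the longer protein. Each filter stage
    is logged separately.
    """
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins for all-vs-all similarity")
    aligner = _local_aligner()
    rng = np.random.default_rng(seed)

    # decoy calibration: local scores of shuffled-sequence pairs
    sequences = [p.sequence for p in proteins]
    decoy_scores = np.empty(n_decoys)
    for d in range(n_decoys):
        sa = list(sequences[rng.integers(len(sequences))])
        sb = list(sequences[rng.integers(len(sequences))])
        rng.shuffle(sa)
        rng.shuffle(sb)
        decoy_scores[d], _, _ = _local_hit(aligner, "".join(sa), "".join(sb))
    calibration = EvalueCalibration.from_decoy_scores(decoy_scores, n_db=len(proteins))

    raw: list[SimilarityHit] = []
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            a, b = proteins[i], proteins[j]
            score, qspan, sspan = _local_hit(aligner, a.sequence, b.sequence)
            longer = max(a.length, b.length)
            span_len = (qspan[1] - qspan[0] + 1) if a.length >= b.length else (sspan[1] - sspan[0] + 1)
            coverage = span_len / longer
            log10e = calibration.log10_evalue(score)
            raw.append(SimilarityHit(
                query_id=a.protein_id, subject_id=b.protein_id,
                query_span=qspan, subject_span=sspan, score=score,
                evalue=10.0 ** max(log10e, -300.0), log10_evalue=log10e,
                coverage_of_longer=coverage,
            ))

    gate = math.log10(config.similarity_evalue)
    passing = [h for h in raw if h.log10_evalue < gate]
    log_filter("similarity e-value gate", len(raw), len(passing), config.similarity_evalue)

    # best-hit ratio: keep hits within the configured factor of the best
    # non-self hit of either endpoint (log-space to dodge underflow)
    best: dict[str, float] = {}
    for h in passing:
        for name in (h.query_id, h.subject_id):
            best[name] = min(best.get(name, math.inf), h.log10_evalue)
    ratio_log = abs(math.log10(config.best_hit_ratio))
    after_ratio = [
        h for h in passing
        if h.log10_evalue <= min(best[h.query_id], best[h.subject_id]) + ratio_log
    ]
    log_filter("similarity best-hit ratio", len(passing), len(after_ratio), config.best_hit_ratio)

    retained = [h for h in after_ratio if h.coverage_of_longer >= config.min_coverage]
    log_filter("similarity coverage", len(after_ratio), len(retained), config.min_coverage)
    return retained


# ---------------------------------------------------------------------------
# Tandem clusters
# ---------------------------------------------------------------------------

@dataclass
class TandemCluster:
    chromosome: str
    members: list[str]  # gene ids in start order
    span: int  # bp from first start to last end

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a tandem cluster needs at least 2 members")


def detect_tandem_clusters(
    genes: list[GeneModel],
    window: int = 200_000,
) -> list[TandemCluster]:
    """Maximal runs of family genes whose consecutive starts lie within ``window``.

    Per chromosome, genes are sorted by start; consecutive genes closer than
    the window are linked and connected runs of two or more genes form one
    cluster (transitive closure, so clusters are the connected components of
    the proximity graph).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    clusters = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        run = [ordered[0]]
        for g in ordered[1:]:
            if g.start - run[-1].start <= window:
                run.append(g)
            else:
                if len(run) >= 2:
                    clusters.append(_make_cluster(chrom, run))
                run = [g]
        if len(run) >= 2:
            clusters.append(_make_cluster(chrom, run))
    logger.info("tandem detection: %d clusters from %d genes (window=%d bp)",
                len(clusters), len(genes), window)
    return clusters


def _make_cluster(chrom: str, run: list[GeneModel]) -> TandemCluster:
    return TandemCluster(
        chromosome=chrom,
        members=[g.gene_id for g in run],
        span=max(g.end for g in run) - min(g.start for g in run) + 1,
    )


# ---------------------------------------------------------------------------
# Collinear block chaining
# ---------------------------------------------------------------------------

@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[tuple[str, str]]  # ordered (geneA, geneB) pairs
    orientation: str  # "same" | "reversed"

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def _chain_dp(points: list[tuple[int, int]], gap: int) -> list[list[int]]:
    """All maximal-score chains by DP; points are (rankA, rankB) anchors.

    Consecutive anchors must strictly advance in rank on both axes with at
    most ``gap`` intervening ranks on each. Returns chains as index lists,
    best-first, each anchor used at most once.
    """
    order = sorted(range(len(points)), key=lambda k: points[k])
    chains: list[list[int]] = []
    used: set[int] = set()
    while True:
        avail = [k for k in order if k not in used]
        if not avail:
            break
        best_len = {k: 1 for k in avail}
        prev = {k: None for k in avail}
        for ii, k in enumerate(avail):
            ra, rb = points[k]
            for kk in avail[:ii]:
                pa, pb = points[kk]
                if pa < ra and pb < rb and (ra - pa - 1) <= gap and (rb - pb - 1) <= gap:
                    if best_len[kk] + 1 > best_len[k]:
                        best_len[k] = best_len[kk] + 1
                        prev[k] = kk
        end = max(avail, key=lambda k: (best_len[k], -points[k][0]))
        chain = []
        node = end
        while node is not None:
            chain.append(node)
            node = prev[node]
        chain.reverse()
        if len(chain) < 2:
            break
        chains.append(chain)
        used.update(chain)
    return chains


def chain_collinear_blocks(
    hits: list[SimilarityHit],
    gene_order: dict[str, list[str]],
    gap: int = 6,
    min_anchors: int = 2,
) -> list[CollinearBlock]:
    """Chain similarity anchors into collinear (segmental-duplication) blocks.

    Anchors are retained hit pairs projected to gene ranks on their
    chromosomes; chains must advance in rank on both chromosomes (both
    orientations tried) with at most ``gap`` intervening non-anchor genes on
    each; chains with at least ``min_anchors`` anchors are emitted and each
    anchor belongs to at most one block (best chain first).
    """
    rank: dict[str, tuple[str, int]] = {}
    for chrom, order in gene_order.items():
        for idx, gid in enumerate(order):
            rank[gid] = (chrom, idx)
    for h in hits:
        for gid in (h.query_id, h.subject_id):
            if gid not in rank:
                raise ValueError(f"gene {gid!r} in hits but missing from gene_order")

    groups: dict[tuple[str, str], list[tuple[int, int, SimilarityHit]]] = {}
    for h in hits:
        ca, ia = rank[h.query_id]
        cb, ib = rank[h.subject_id]
        if ca == cb and abs(ia - ib) <= gap + 1:
            continue  # local (tandem-range) pair, not a segmental anchor

        if (ca, ia) <= (cb, ib):
            key, pa, pb = (ca, cb), ia, ib
            anchor = (h.query_id, h.subject_id)
        else:
            key, pa, pb = (cb, ca), ib, ia
            anchor = (h.subject_id, h.query_id)
        groups.setdefault(key, []).append((pa, pb, anchor))

    blocks: list[CollinearBlock] = []
    for (ca, cb), group in sorted(groups.items()):
        remaining = group
        for orientation in ("same", "reversed"):
            pts = [(pa, pb if orientation == "same" else -pb) for pa, pb, _ in remaining]
            chains = _chain_dp(pts, gap)
            taken: set[int] = set()
            for chain in chains:
                if len(chain) < min_anchors:
                    continue
                taken.update(chain)
                blocks.append(CollinearBlock(
                    chrom_a=ca, chrom_b=cb,
                    anchors=[remaining[k][2] for k in chain],
                    orientation=orientation,
                ))
            # anchors consumed in this orientation are not reused in the next
            remaining = [a for k, a in enumerate(remaining) if k not in taken]
    result = sorted(blocks, key=lambda b: (-b.n_anchors, b.chrom_a, b.chrom_b, b.anchors))
    logger.info("collinearity: %d blocks from %d hits (gap=%d, min_anchors=%d)",
                len(result), len(hits), gap, min_anchors)
    return result
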