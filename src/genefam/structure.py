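"""Exon/intron categorization and de-novo motif discovery.

Family genes are binned by intron count into the three categories the
family analysis uses (intronless / single intron / multiple introns).
Conserved protein motifs are found de novo with a ZOOPS
(zero-or-one-occurrence-per-sequence) expectation-maximization model: up to
``max_motifs`` motifs of width 8-100 are extracted one at a time, each
converged motif's occurrences are masked before the next search, and the
scan stops when the best remaining motif carries less than 0.5 bits of
information per column.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .domain import AA_INDEX, AMINO_ACIDS, DomainProfile, calibrate_profile, encode_protein, scan_protein
from .io import GeneModel, ProteinRecord

logger = logging.getLogger("genefam")

WIDTH_GRID = (8, 12, 16, 21, 29, 41, 58, 81, 100)
IC_STOP = 0.5  # bits/column below which no further motif is reported
EM_RESTARTS = 10
EM_MAX_ITER = 200
EM_TOL = 1e-6


# ---------------------------------------------------------------------------
# Intron categories
# ---------------------------------------------------------------------------

@dataclass
class IntronClass:
    gene_id: str
    intron_count: int
    category: str  # intronless | single_intron | multiple_introns


def classify_intron_counts(genes: list[GeneModel]) -> tuple[list[IntronClass], dict[str, int]]:
    """Intron count and category per gene, plus the category tally."""
    classes = []
    tally = {"intronless": 0, "single_intron": 0, "multiple_introns": 0}
    for gene in genes:
        if len(gene.exons) == 0:
            raise ValueError(f"gene {gene.gene_id} has no exons")
        count = len(gene.exons) - 1
        category = "intronless" if count == 0 else "single_intron" if count == 1 else "multiple_introns"
        classes.append(IntronClass(gene.gene_id, count, category))
        tally[category] += 1
    logger.info("intron categories: %s from %d genes", tally, len(genes))
    return classes, tally


# ---------------------------------------------------------------------------
# ZOOPS EM motif discovery
# ---------------------------------------------------------------------------

@dataclass
class MotifModel:
    motif_id: int
    width: int
    frequencies: np.ndarray  # (width, 20), columns sum to 1
    occurrences: list[tuple[str, int, float]] = field(default_factory=list)  # (seq id, 1-based start, score)
    ic_per_column: float = 0.0

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        return np.log2(self.frequencies / background)

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.frequencies.argmax(axis=1))


def _window_log_ratios(enc: np.ndarray, mask: np.ndarray, log_ratio: np.ndarray, w: int) -> np.ndarray:
    """Per-window motif/background log-likelihood ratios; masked windows -inf."""
    if enc.size < w:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    scores = log_ratio[np.arange(w), windows].sum(axis=1)
    masked = np.lib.stride_tricks.sliding_window_view(mask, w).any(axis=1)
    scores[masked] = -np.inf
    return scores


def _zoops_em(
    encoded: list[np.ndarray],
    masks: list[np.ndarray],
    width: int,
    background: np.ndarray,
    rng: np.random.Generator,
    pseudocount: float = 0.5,
) -> tuple[np.ndarray, float, float, np.ndarray]:
    """One EM run; returns (pfm, log-likelihood, gamma, soft counts)."""
    # init from a random unmasked window, heavily smoothed
    starts = [(i, j) for i, (e, m) in enumerate(zip(encoded, masks))
              for j in range(len(e) - width + 1)
              if not m[j : j + width].any()]
    if not starts:
        return np.tile(background, (width, 1)), -np.inf, 0.0, np.zeros((width, 20))
    si, sj = starts[rng.integers(len(starts))]
    pfm = np.tile(background, (width, 1)).copy()
    seed_window = encoded[si][sj : sj + width]
    for k, aa in enumerate(seed_window):
        if aa < 20:
            pfm[k] = 0.5 * pfm[k]
            pfm[k, aa] += 0.5
    gamma = 0.5
    prev_objective = -np.inf
    ll = -np.inf
    for _ in range(EM_MAX_ITER):
        log_ratio = np.hstack([np.log(pfm / background), np.zeros((width, 1))])
        # Jeffreys +0.5/residue smoothing prior; EM is monotone in ll + prior
        prior = pseudocount * float(np.log(pfm).sum())
        counts = np.zeros((width, 20))
        gamma_new = 0.0
        ll = 0.0
        n_seq = 0
        for enc, mask in zip(encoded, masks):
            scores = _window_log_ratios(enc, mask, log_ratio, width)
            if scores.size == 0:
                continue
            n_seq += 1
            m = scores.size
            finite = np.isfinite(scores)
            if not finite.any():
                ll += math.log(max(1.0 - gamma, 1e-300))
                continue
            # P(seq) = (1-gamma)*B + (gamma/m) * sum_j B*exp(score_j)
            smax = scores[finite].max()
            ratio_sum = np.exp(scores[finite] - smax).sum()
            log_motif_term = math.log(gamma / m) + smax + math.log(ratio_sum)
            log_null_term = math.log(max(1.0 - gamma, 1e-300))
            big = max(log_motif_term, log_null_term)
            ll += big + math.log(math.exp(log_motif_term - big) + math.exp(log_null_term - big))
            # posterior over windows
            z = np.zeros(m)
            z[finite] = np.exp(scores[finite] - smax)
            z *= (gamma / m) * math.exp(smax - big)
            z /= math.exp(log_motif_term - big) + math.exp(log_null_term - big)
            gamma_new += z.sum()
            nz = np.flatnonzero(z > 1e-12)
            for j in nz:
                window = enc[j : j + width]
                valid = window < 20
                counts[np.arange(width)[valid], window[valid]] += z[j]
        if n_seq == 0:
            return np.tile(background, (width, 1)), -np.inf, 0.0, np.zeros((width, 20))
        objective = ll + prior
        if objective < prev_objective - 1e-6:
            raise AssertionError(
                f"EM objective decreased: {prev_objective} -> {objective}"
            )
        gamma = min(max(gamma_new / n_seq, 1e-6), 1.0 - 1e-6)
        pfm = (counts + pseudocount) / (
            counts.sum(axis=1, keepdims=True) + 20.0 * pseudocount
        )
        if abs(objective - prev_objective) < EM_TOL:
            break
        prev_objective = objective
    return pfm, ll, gamma, counts


def _ic_per_column(counts: np.ndarray, background: np.ndarray, mean_windows: float) -> float:
    """Bias-corrected information per column (bits) of a converged motif.

    Raw IC is KL(motif || background) of the maximum-likelihood column
    frequencies (the EM soft counts, unsmoothed). Two inflation sources are
    subtracted: the Miller-Madow small-sample entropy bias
    (K-1)/(2 N ln 2) for N effective occurrences, and the order-statistic
    cost log2(m)/width of EM having chosen the best-looking of m windows
    per sequence. Together they make EM-converged "motifs" on pure
    background score near zero, so the 0.5-bit stop rule is discriminative
    while genuinely shared motifs stay well above it.
    """
    totals = counts.sum(axis=1, keepdims=True)
    n_eff = float(totals.mean())
    if n_eff <= 0:
        return -math.inf
    mle = np.where(totals > 0, counts / np.maximum(totals, 1e-300), background)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(mle > 0, mle * np.log2(mle / background), 0.0)
    raw = float(terms.sum(axis=1).mean())
    width = counts.shape[0]
    small_sample = 19.0 / (2.0 * math.log(2.0) * max(n_eff, 1.0))
    selection = math.log2(max(mean_windows, 2.0)) / width
    return raw - small_sample - selection


def discover_motifs(
    proteins: list[ProteinRecord],
    max_motifs: int = 8,
    width_range: tuple[int, int] = (8, 100),
    seed: int = 0,
) -> list[MotifModel]:
    """Iterative ZOOPS EM motif discovery with post-motif masking.

    Widths are scanned over a coarse grid within ``width_range`` (10 seeded
    restarts each, best likelihood kept per width; the winning width by
    information content). Discovery stops at ``max_motifs`` or when the best
    candidate falls below {IC_STOP} bits/column.
    """
    if len(proteins) < 5:
        raise ValueError("need at least 5 sequences for motif discovery")
    encoded = [encode_protein(p.sequence) for p in proteins]
    min_w = min(w for w in WIDTH_GRID if w >= width_range[0]) if any(
        w >= width_range[0] for w in WIDTH_GRID) else width_range[0]
    if all(len(e) < min_w for e in encoded):
        raise ValueError("all sequences shorter than the minimum motif width")
    masks = [np.zeros(len(e), dtype=bool) for e in encoded]
    rng = np.random.default_rng(seed)

    motifs: list[MotifModel] = []
    widths = [w for w in WIDTH_GRID if width_range[0] <= w <= width_range[1]]
    for motif_id in range(1, max_motifs + 1):
        # background from unmasked residues
        counts = np.zeros(20)
        for enc, mask in zip(encoded, masks):
            free = enc[(~mask) & (enc < 20)]
            counts += np.bincount(free, minlength=20)
        background = (counts + 1.0) / (counts.sum() + 20.0)

        best: tuple[float, np.ndarray, int] | None = None  # (ic, pfm, width)
        for width in widths:
            usable = [len(e) >= width for e in encoded]
            if sum(usable) < 2:
                continue
            best_ll = -np.inf
            best_pfm = None
            best_counts = None
            for _ in range(EM_RESTARTS):
                pfm, ll, gamma, counts = _zoops_em(encoded, masks, width, background, rng)
                if ll > best_ll:
                    best_ll, best_pfm, best_counts = ll, pfm, counts
            if best_pfm is None:
                continue
            mean_windows = float(np.mean([
                len(e) - width + 1 for e, u in zip(encoded, usable) if u
            ]))
            ic = _ic_per_column(best_counts, background, mean_windows)
            if best is None or ic > best[0]:
                best = (ic, best_pfm, width)
        if best is None or best[0] < IC_STOP:
            break
        ic, pfm, width = best
        motif = MotifModel(motif_id=motif_id, width=width, frequencies=pfm, ic_per_column=ic)

        # final E-step to place occurrences, then mask them
        log_ratio = np.hstack([np.log(pfm / background), np.zeros((width, 1))])
        for p, enc, mask in zip(proteins, encoded, masks):
            scores = _window_log_ratios(enc, mask, log_ratio, width)
            if scores.size == 0 or not np.isfinite(scores).any():
                continue
            j = int(np.argmax(scores))
            if scores[j] > 0:  # more likely under the motif than background
                motif.occurrences.append((p.protein_id, j + 1, float(scores[j])))
                mask[j : j + width] = True
        motifs.append(motif)
        logger.info("motif %d: width %d, IC %.2f bits/col, %d occurrences",
                    motif_id, width, ic, len(motif.occurrences))
    return motifs


def map_motifs(
    motifs: list[MotifModel],
    proteins: list[ProteinRecord],
    evalue_threshold: float = 0.05,
    n_decoys: int = 2000,
    seed: int = 0,
) -> list[tuple[str, int, int, int, float, float]]:
    """Scan proteins with each motif's log-odds profile.

    Occurrences above the per-motif decoy-calibrated threshold are reported
    as (protein_id, motif_id, start, end, score, evalue) rows.
    """
    if not motifs:
        return []
    sequences = [p.sequence for p in proteins]
    table: list[tuple[str, int, int, int, float, float]] = []
    for motif in motifs:
        counts = np.zeros(20)
        for s in sequences:
            enc = encode_protein(s)
            counts += np.bincount(enc[enc < 20], minlength=20)
        background = (counts + 1.0) / (counts.sum() + 20.0)
        profile = DomainProfile(
            width=motif.width,
            log_odds=np.log2(motif.frequencies / background),
            background=background,
        )
        calibrate_profile(profile, n_decoys=n_decoys, seed=seed,
                          database_sequences=[s for s in sequences if len(s) >= motif.width])
        for protein in proteins:
            for hit in scan_protein(profile, protein, evalue_threshold=evalue_threshold):
                table.append((protein.protein_id, motif.motif_id, hit.start, hit.end,
                              hit.score, hit.evalue))
    return table
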