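"""Family identification by profile scan against a conserved-domain model.

The family-membership criterion is the presence of exactly one copy of the
~100-residue alpha-crystallin domain (ACD) that defines small heat-shock
proteins. The search tool's profile-HMM is replaced here by a gapless
position-specific log-odds profile with an explicit decoy-calibrated e-value
(see :mod:`genefam.calibration`): the domain is compact and well conserved,
so a gapless profile captures the discrimination the pipeline needs while
remaining fully testable. Proteins with no passing domain hit are rejected,
as are proteins with two or more non-overlapping hits (multi-domain
architectures fall outside the family definition).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

from .calibration import EvalueCalibration
from .io import GeneModel, ProteinRecord, ValidationError, log_filter

logger = logging.getLogger("genefam")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
UNIFORM_BACKGROUND = np.full(20, 1 / 20)

# Average (isotope-averaged) residue masses in Daltons; one water is added
# per chain. X contributes the mean residue mass and is excluded from charge.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153
MEAN_RESIDUE_MASS = sum(RESIDUE_MASS.values()) / len(RESIDUE_MASS)


def encode_protein(sequence: str) -> np.ndarray:
    """Map residues to 0..19; X and other ambiguity codes to 20."""
    return np.array([AA_INDEX.get(ch, 20) for ch in sequence.upper()], dtype=np.int64)


@dataclass
class DomainProfile:
    """Position-specific log-odds profile (bits) over the 20 amino acids."""

    width: int
    log_odds: np.ndarray  # (width, 20)
    background: np.ndarray  # (20,)
    calibration: EvalueCalibration | None = None

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.log_odds.shape != (self.width, 20):
            raise ValidationError("log_odds grid shape mismatches width")
        if not np.isfinite(self.log_odds).all():
            raise ValidationError("non-finite log-odds score")
        if (self.background <= 0).any():
            raise ValidationError("background frequencies must be > 0")

    @property
    def scoring_matrix(self) -> np.ndarray:
        """log_odds with an extra all-zero column so X scores 0 everywhere."""
        return np.hstack([self.log_odds, np.zeros((self.width, 1))])

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.log_odds.argmax(axis=1))


@dataclass
class DomainHit:
    protein_id: str
    start: int  # 1-based inclusive residue position
    end: int
    score: float  # bits
    evalue: float

    def overlaps(self, other: "DomainHit") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class FamilyMember:
    protein: ProteinRecord
    hits: list[DomainHit] = field(default_factory=list)
    gene: GeneModel | None = None
    status: str = "pending"  # accepted | rejected_no_domain | rejected_multi_domain


def build_profile(
    seed_alignment: list[str],
    background: np.ndarray | None = None,
    pseudocount: float = 0.5,
    max_gap_fraction: float = 0.5,
) -> DomainProfile:
    """Build a log-odds profile from a gapped seed alignment.

    Columns with more than ``max_gap_fraction`` gaps are dropped. Per
    position, log-odds (bits) = log2(((counts + pseudocount)/total) /
    background) with a Jeffreys +0.5 pseudocount per residue.
    """
    if len(seed_alignment) == 0:
        raise ValueError("empty seed alignment")
    if len({len(row) for row in seed_alignment}) != 1:
        raise ValueError("seed alignment rows differ in length")
    background = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    n_cols = len(seed_alignment[0])
    columns = []
    for j in range(n_cols):
        residues = [row[j].upper() for row in seed_alignment]
        gap_fraction = sum(r in "-." for r in residues) / len(residues)
        if gap_fraction > max_gap_fraction:
            continue
        counts = np.zeros(20)
        for r in residues:
            idx = AA_INDEX.get(r)
            if idx is not None:
                counts[idx] += 1
        total = counts.sum() + 20 * pseudocount
        freqs = (counts + pseudocount) / total
        columns.append(np.log2(freqs / background))
    if not columns:
        raise ValueError("no columns retained from seed alignment")
    log_odds = np.vstack(columns)
    return DomainProfile(width=log_odds.shape[0], log_odds=log_odds, background=background)


def window_scores(profile: DomainProfile, encoded: np.ndarray) -> np.ndarray:
    """Score every length-``width`` window of an encoded protein (bits)."""
    w = profile.width
    if encoded.size < w:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, w)
    return profile.scoring_matrix[np.arange(w), windows].sum(axis=1)


def _best_window_scores(profile: DomainProfile, decoys: np.ndarray) -> np.ndarray:
    """Best window score per decoy row; decoys is an (n, L) int array."""
    scoring = profile.scoring_matrix
    w = profile.width
    out = np.empty(decoys.shape[0])
    chunk = max(1, 2_000_000 // max(decoys.shape[1] * w, 1))
    for lo in range(0, decoys.shape[0], chunk):
        block = decoys[lo : lo + chunk]
        windows = np.lib.stride_tricks.sliding_window_view(block, w, axis=1)
        out[lo : lo + chunk] = scoring[np.arange(w), windows].sum(axis=2).max(axis=1)
    return out


def calibrate_profile(
    profile: DomainProfile,
    n_decoys: int = 10_000,
    decoy_length: int | None = None,
    seed: int = 0,
    database_sequences: list[str] | None = None,
) -> DomainProfile:
    """Attach an e-value calibration from a decoy scan.

    Decoys are residue shuffles of database sequences when provided, else
    i.i.d. draws from the profile background; e-value(s) is scaled to the
    decoy database size (``n_db = n_decoys``).
    """
    rng = np.random.default_rng(seed)
    length = decoy_length or max(2 * profile.width, profile.width + 20)
    if database_sequences:
        pool = [encode_protein(s) for s in database_sequences if len(s) >= profile.width]
        if not pool:
            raise ValueError("no database sequence is as long as the profile")
        decoys = np.stack([
            rng.permuted(np.resize(pool[rng.integers(len(pool))], length))
            for _ in range(n_decoys)
        ])
    else:
        decoys = rng.choice(20, size=(n_decoys, length), p=profile.background)
    scores = _best_window_scores(profile, decoys)
    profile.calibration = EvalueCalibration.from_decoy_scores(scores, n_db=n_decoys)
    return profile


def scan_protein(
    profile: DomainProfile,
    protein: ProteinRecord,
    evalue_threshold: float = 1e-10,
) -> list[DomainHit]:
    """Report non-overlapping domain hits passing the e-value gate.

    All windows are scored; windows at or above the score corresponding to
    ``evalue_threshold`` are kept and overlapping candidates are resolved to
    the best-scoring window (leftmost on ties).
    """
    if profile.calibration is None:
        raise ValueError("profile has no e-value calibration; run calibrate_profile first")
    encoded = encode_protein(protein.sequence)
    if encoded.size < profile.width:
        logger.warning(
            "protein %s (len %d) shorter than profile width %d; no scan",
            protein.protein_id, encoded.size, profile.width,
        )
        return []
    scores = window_scores(profile, encoded)
    min_score = profile.calibration.score_at(evalue_threshold)
    candidates = np.flatnonzero(scores >= min_score)
    # best-score-first greedy resolution of overlaps; leftmost wins ties
    order = sorted(candidates, key=lambda i: (-scores[i], i))
    hits: list[DomainHit] = []
    for i in order:
        hit = DomainHit(
            protein_id=protein.protein_id,
            start=int(i) + 1,
            end=int(i) + profile.width,
            score=float(scores[i]),
            evalue=profile.calibration.evalue(float(scores[i])),
        )
        if not any(hit.overlaps(h) for h in hits):
            hits.append(hit)
    hits.sort(key=lambda h: h.start)
    return hits


def select_family_members(candidates: list[FamilyMember]) -> list[FamilyMember]:
    """Classify scanned candidates by hit count.

    0 hits -> rejected_no_domain; exactly 1 -> accepted; >= 2 non-overlapping
    passing hits -> rejected_multi_domain. Classification is total; counts of
    each class are logged.
    """
    tally = {"accepted": 0, "rejected_no_domain": 0, "rejected_multi_domain": 0}
    for member in candidates:
        if len(member.hits) == 0:
            member.status = "rejected_no_domain"
        elif len(member.hits) == 1:
            member.status = "accepted"
        else:
            member.status = "rejected_multi_domain"
        tally[member.status] += 1
    logger.info(
        "domain selection: %d candidates -> %d accepted, %d no-domain, %d multi-domain",
        len(candidates), tally["accepted"],
        tally["rejected_no_domain"], tally["rejected_multi_domain"],
    )
    log_filter("domain selection", len(candidates), tally["accepted"], "exactly one domain")
    return candidates


def net_charge(sequence: str, pH: float) -> float:
    """Net charge of a protein at a given pH (Henderson-Hasselbalch)."""
    clean = "".join(ch for ch in sequence.upper() if ch in AA_INDEX)
    return IsoelectricPoint(clean).charge_at_pH(pH)


def compute_protein_stats(sequence: str) -> tuple[int, float, float]:
    """(length, molecular weight in Da, isoelectric point).

    MW sums average residue masses plus one water; X contributes the mean
    residue mass. pI is solved by bisection on the net charge with the
    Bjellqvist pKa set, to |charge| well below 1e-4; X is excluded from the
    charge computation.
    """
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("empty sequence")
    mw = WATER_MASS
    for ch in sequence:
        mw += RESIDUE_MASS.get(ch, MEAN_RESIDUE_MASS)
    clean = "".join(ch for ch in sequence if ch in AA_INDEX)
    if not clean:
        raise ValueError("sequence contains no standard residues")
    # net charge is strictly decreasing in pH, so bisect on [0, 14]
    ip = IsoelectricPoint(clean)
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(60):
        mid = (lo + hi) / 2
        q = ip.charge_at_pH(mid)
        if abs(q) < 1e-6:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return len(sequence), mw, mid
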