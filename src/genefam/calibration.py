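"""Empirical e-value calibration from decoy score distributions.

Search tools report e-values from analytic Karlin-Altschul statistics; this
package instead calibrates each scoring system explicitly: score a decoy
database, fit a Gumbel (extreme-value) distribution to the per-decoy maximum
scores, and report e-value(s) = N_db * P(score >= s). The Gumbel family is
the asymptotic law of maxima of i.i.d. window scores, so extrapolation to
tail probabilities far below 1/N_decoys (e.g. the 1e-10 and 1e-20 gates) is
principled, and the calibration is directly testable against decoy counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class EvalueCalibration:
    """Gumbel fit to decoy maxima; converts scores to e-values and back."""

    loc: float
    scale: float
    n_db: int  # database size the e-value is scaled to

    def evalue(self, score: float) -> float:
        return float(self.n_db * stats.gumbel_r.sf(score, self.loc, self.scale))

    def log10_evalue(self, score: float) -> float:
        """log10 of the e-value; immune to underflow for very high scores."""
        logsf = stats.gumbel_r.logsf(score, self.loc, self.scale)
        return float((logsf + np.log(self.n_db)) / np.log(10.0))

    def score_at(self, evalue: float) -> float:
        """Score whose e-value equals ``evalue`` (monotone inverse)."""
        p = min(evalue / self.n_db, 1.0 - 1e-12)
        return float(stats.gumbel_r.isf(p, self.loc, self.scale))

    @classmethod
    def from_decoy_scores(cls, scores: np.ndarray, n_db: int) -> "EvalueCalibration":
        scores = np.asarray(scores, dtype=float)
        if scores.size < 10:
            raise ValueError("need at least 10 decoy scores for a stable Gumbel fit")
        loc, scale = stats.gumbel_r.fit(scores)
        if scale <= 0:  # degenerate decoys (all-equal scores)
            scale = 1e-6
        return cls(loc=loc, scale=scale, n_db=n_db)
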