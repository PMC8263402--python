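"""Logistic disease-risk model with a dominant genetic effect.

The disease model is the hinge between the synthetic-data generator (case
ascertainment), the exposure-probability derivation and the power
calculations.  Disease risk for carrier status ``g`` (dominant coding: 1 for
one or two copies of the minor allele) and binary exposure ``e`` is

    odds(D = 1 | g, e) = baseline_odds * or_g**g * or_e**e * or_ge**(g*e)

with ``P = odds / (1 + odds)``.  ``baseline_odds`` is the disease odds for an
unexposed non-carrier; a small value (default 0.001) encodes the
rare-disease assumption on which the case-only design rests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["DiseaseModel"]


@dataclass(frozen=True)
class DiseaseModel:
    """Parameters of the logistic disease model (dominant genetic coding).

    Parameters
    ----------
    baseline_odds
        Disease odds for an unexposed non-carrier; > 0 and small for a rare
        disease.
    or_g, or_e, or_ge
        Odds ratios for the genetic main effect (dominant carrier status),
        the environmental main effect and the multiplicative G×E
        interaction; all > 0.
    maf
        Minor-allele frequency of the target SNP in the source population,
        in (0, 0.5].
    p_exposure
        Population frequency of the binary exposure, in (0, 1).
    """

    baseline_odds: float = 1e-3
    or_g: float = 1.0
    or_e: float = 1.0
    or_ge: float = 1.0
    maf: float = 0.25
    p_exposure: float = 0.1

    def __post_init__(self) -> None:
        for name in ("baseline_odds", "or_g", "or_e", "or_ge"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be a positive finite number, got {value!r}")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must lie in (0, 0.5], got {self.maf!r}")
        if not 0.0 < self.p_exposure < 1.0:
            raise ValueError(f"p_exposure must lie in (0, 1), got {self.p_exposure!r}")
        table = self.penetrance_table()
        if not np.all((table > 0.0) & (table < 1.0)):
            raise ValueError("disease model implies degenerate P(D=1|G,E) in some cell")

    def penetrance(self, g, e) -> np.ndarray:
        """P(D = 1 | carrier status g, exposure e) for g, e in {0, 1}."""
        g = np.asarray(g, dtype=float)
        e = np.asarray(e, dtype=float)
        logit = (
            np.log(self.baseline_odds)
            + g * np.log(self.or_g)
            + e * np.log(self.or_e)
            + g * e * np.log(self.or_ge)
        )
        return expit(logit)

    def penetrance_table(self) -> np.ndarray:
        """2x2 array of P(D=1|g,e): rows index g in {0,1}, columns e in {0,1}."""
        return self.penetrance([[0], [1]], [[0, 1]])

    def carrier_freq(self) -> float:
        """Population frequency of dominant carriers, 1 - (1 - maf)**2."""
        return 1.0 - (1.0 - self.maf) ** 2

    def replace(self, **changes) -> "DiseaseModel":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)
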