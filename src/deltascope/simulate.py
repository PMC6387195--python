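"""Stochastic single-cell transcript simulator with a probe-detection model.

Per-cell transcript totals follow a zero-inflated negative binomial (ZINB):
with probability ``silent_fraction`` a cell is transcriptionally silent
(zero transcripts); otherwise the total T is negative binomial with mean
``expr_mean * nmd_multiplier`` and dispersion ``dispersion`` (variance
mu + mu^2/k, Poisson as k -> inf).  This is the simplest model consistent
with bursty, punctuated expression: a large silent cell fraction alongside
heavily overdispersed counts in the expressing cells.  Each transcript is
independently the exon-skipping (delta) isoform with probability
``delta_fraction``.

Detection maps true states to observed two-channel counts: the C1 probe
sees full-length transcripts only (Binomial(n_full, eff_c1)), the C2 probe
sees every transcript (Binomial(n_full + n_delta, eff_c2)); each channel
adds Poisson background at its own rate, unpaired between channels, so
observed c1 > c2 is possible — as seen in real assays.

All randomness flows from ``SimParams.seed`` (or an explicit ``seed``
argument); each pipeline stage draws from its own seeded stream, with
per-cell draws vectorised in cell-index order, so outputs are reproducible
byte for byte.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .scoring import CellCount

__all__ = [
    "SimParams",
    "TrueCellState",
    "simulate_true_cells",
    "apply_detection",
    "simulate_counts",
    "nb_zero_prob",
    "calibrate_zinb",
    "get_preset",
    "PRESET_NAMES",
    "UNTREATED_FOLD_CHANGE",
]

# Stage tags keeping the per-stage random streams distinct for one seed.
_STAGE_TRUE = 1
_STAGE_DETECT = 2


class ParameterError(ValueError):
    """A simulation parameter is non-finite or out of range."""


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for the single-cell expression simulator.

    Parameters
    ----------
    silent_fraction:
        Probability in [0, 1] that a cell carries zero transcripts.
    expr_mean:
        Mean transcripts per (non-silent) cell, in molecules.
    dispersion:
        Negative-binomial dispersion k > 0; variance is mu + mu^2/k.
    delta_fraction:
        Probability in [0, 1] that a transcript is the delta isoform.
    eff_c1, eff_c2:
        Per-molecule detection probabilities for each channel.
    bg_rate_c1, bg_rate_c2:
        Mean false signals per cell per channel (Poisson, >= 0).
    nmd_multiplier:
        Scalar >= 0 applied to ``expr_mean``; models inhibition of
        nonsense-mediated decay (treated cells retain more transcripts).
    seed:
        Integer seeding every random stream derived from these parameters.
    """

    silent_fraction: float
    expr_mean: float
    dispersion: float
    delta_fraction: float
    eff_c1: float = 1.0
    eff_c2: float = 1.0
    bg_rate_c1: float = 0.0
    bg_rate_c2: float = 0.0
    nmd_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        probs = {
            "silent_fraction": self.silent_fraction,
            "delta_fraction": self.delta_fraction,
            "eff_c1": self.eff_c1,
            "eff_c2": self.eff_c2,
        }
        for name, v in probs.items():
            if not math.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be a probability in [0, 1], got {v}")
        nonneg = {
            "expr_mean": self.expr_mean,
            "bg_rate_c1": self.bg_rate_c1,
            "bg_rate_c2": self.bg_rate_c2,
            "nmd_multiplier": self.nmd_multiplier,
        }
        for name, v in nonneg.items():
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {v}")
        if not math.isfinite(self.dispersion) or self.dispersion <= 0:
            raise ParameterError(f"dispersion must be > 0, got {self.dispersion}")
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise ParameterError(f"seed must be an integer, got {self.seed!r}")

    @property
    def effective_mean(self) -> float:
        return self.expr_mean * self.nmd_multiplier

    def with_seed(self, seed: int) -> "SimParams":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class TrueCellState:
    """Latent transcript content of one simulated cell."""

    cell_id: str
    n_full: int
    n_delta: int

    def __post_init__(self) -> None:
        if self.n_full < 0 or self.n_delta < 0:
            raise ValueError("transcript counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_full + self.n_delta


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def simulate_true_cells(
    params: SimParams, n_cells: int, sample: str = "sim"
) -> list[TrueCellState]:
    """Draw latent per-cell transcript states under the ZINB model.

    Each cell is silent with probability ``silent_fraction``; otherwise its
    transcript total is NB(mean = expr_mean * nmd_multiplier, dispersion k)
    and the delta-isoform count is Binomial(total, delta_fraction).
    """
    params.validate()
    if n_cells <= 0:
        raise ParameterError(f"n_cells must be positive, got {n_cells}")
    rng = _rng(params.seed, _STAGE_TRUE)

    silent = rng.random(n_cells) < params.silent_fraction
    mu = params.effective_mean
    k = params.dispersion
    if mu > 0:
        totals = rng.negative_binomial(n=k, p=k / (k + mu), size=n_cells)
    else:
        totals = np.zeros(n_cells, dtype=np.int64)
    totals = np.where(silent, 0, totals)
    n_delta = rng.binomial(totals, params.delta_fraction)
    width = max(2, len(str(n_cells - 1)))
    return [
        TrueCellState(
            cell_id=f"{sample}_c{i:0{width}d}",
            n_full=int(t - d),
            n_delta=int(d),
        )
        for i, (t, d) in enumerate(zip(totals, n_delta))
    ]


def apply_detection(
    true_cells: Sequence[TrueCellState],
    params: SimParams,
    sample: str = "sim",
) -> list[CellCount]:
    """Map latent transcript states to observed two-channel signal counts.

    C1 detects full-length transcripts only; C2 detects all transcripts.
    Channel backgrounds are independent Poisson draws, so an observed
    c1 > c2 (discordant cell) is possible when background or detection
    asymmetry favours C1.
    """
    params.validate()
    rng = _rng(params.seed, _STAGE_DETECT)
    n_full = np.array([c.n_full for c in true_cells], dtype=np.int64)
    n_total = np.array([c.total for c in true_cells], dtype=np.int64)
    n = len(true_cells)
    c1 = rng.binomial(n_full, params.eff_c1) + rng.poisson(params.bg_rate_c1, size=n)
    c2 = rng.binomial(n_total, params.eff_c2) + rng.poisson(params.bg_rate_c2, size=n)
    return [
        CellCount(cell_id=tc.cell_id, sample=sample, c1=int(a), c2=int(b))
        for tc, a, b in zip(true_cells, c1, c2)
    ]


def simulate_counts(
    params: SimParams, n_cells: int, sample: str = "sim"
) -> tuple[list[TrueCellState], list[CellCount]]:
    """Convenience: latent states plus their observed counts in one call."""
    true_cells = simulate_true_cells(params, n_cells, sample=sample)
    return true_cells, apply_detection(true_cells, params, sample=sample)


# ---------------------------------------------------------------------------
# Preset calibration


def nb_zero_prob(mu: float, k: float) -> float:
    """P(X = 0) for a negative binomial with mean mu and dispersion k."""
    if mu == 0:
        return 1.0
    return float((k / (k + mu)) ** k)


def calibrate_zinb(
    expressing_fraction: float,
    mean_transcripts_per_expressing: float,
    dispersion: float,
) -> tuple[float, float]:
    """Moment-match (silent_fraction, expr_mean) to observed marginals.

    Solves for the NB mean mu such that E[T | T > 0] = mu / (1 - NB0(mu, k))
    matches the observed mean among expressing cells, then sets the silent
    fraction so that P(T > 0) = (1 - pi) * (1 - NB0) equals the observed
    expressing fraction exactly.
    """
    from scipy.optimize import brentq

    f = expressing_fraction
    m = mean_transcripts_per_expressing
    k = dispersion
    if not 0 < f < 1:
        raise ParameterError(f"expressing fraction must be in (0, 1), got {f}")
    if m <= 0:
        raise ParameterError(f"mean per expressing cell must be > 0, got {m}")

    def gap(mu: float) -> float:
        return mu / (1.0 - nb_zero_prob(mu, k)) - m

    # E[T | T>0] > max(mu, 1) and -> m as mu grows, so bracket generously.
    mu = brentq(gap, 1e-9, 10.0 * m)
    pi = 1.0 - f / (1.0 - nb_zero_prob(mu, k))
    if pi < 0:
        raise ParameterError(
            "observed expressing fraction exceeds what the NB component allows"
        )
    return float(pi), float(mu)


# Observed per-sample marginals used for moment matching: fraction of the 50
# scored cells expressing the gene, mean transcripts per expressing cell
# (inferred from the all-transcript channel), and the delta-isoform fraction
# of those transcripts.  With perfect detection the channel totals satisfy
# sum(c1) + sum(c2) = (2 - delta) * T_total and sum(delta events) =
# delta * T_total, which inverts the published totals to transcript space.
_PRESET_MARGINALS: dict[str, dict[str, float]] = {
    # 22/50 expressing; 104 signals, 26 delta -> 65 transcripts
    "BRCA1_carrier": {"f_expr": 0.44, "mean_expr": 65 / 22, "delta": 26 / 65},
    # 2/50 expressing; 13 signals, 5 delta -> 9 transcripts
    "BRCA1_control": {"f_expr": 0.04, "mean_expr": 9 / 2, "delta": 5 / 9},
    # 29/50 expressing; 160 signals, 71 delta -> 115.5 transcripts
    "BRCA2_carrier": {"f_expr": 0.58, "mean_expr": 115.5 / 29, "delta": 71 / 115.5},
    # 12/50 expressing; 31 signals, 7 delta -> 19 transcripts
    "BRCA2_control": {"f_expr": 0.24, "mean_expr": 19 / 12, "delta": 7 / 19},
}

# Dispersion for presets: small k gives the heavy right tail (single cells
# up to ~25 molecules against means of 2-4) seen in the counted data.
_PRESET_DISPERSION = 0.8

PRESET_NAMES = tuple(sorted(_PRESET_MARGINALS))

# Reported fold change in mean molecules per cell of NMD-inhibitor treated
# versus untreated cultures.  The underlying untreated per-cell counts were
# never published, so these multipliers are NOT calibrated against any
# distribution; dividing a preset's mean by its fold change gives only a
# rough untreated scenario.
UNTREATED_FOLD_CHANGE: dict[str, float] = {
    "BRCA1_carrier": 5.2,
    "BRCA1_control": 1.2,
    "BRCA2_carrier": 1.6,
    "BRCA2_control": 4.4,
}


def get_preset(name: str, seed: int = 0, treated: bool = True) -> SimParams:
    """Return the moment-matched parameter preset for one study sample.

    Presets describe NMD-inhibitor treated cultures (the condition the
    published counts come from).  ``treated=False`` rescales the mean by the
    reported fold change to sketch the untreated culture; this is
    uncalibrated (no untreated per-cell data exists) and warns accordingly.
    """
    if name not in _PRESET_MARGINALS:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        )
    m = _PRESET_MARGINALS[name]
    pi, mu = calibrate_zinb(m["f_expr"], m["mean_expr"], _PRESET_DISPERSION)
    nmd = 1.0
    if not treated:
        nmd = 1.0 / UNTREATED_FOLD_CHANGE[name]
        warnings.warn(
            f"untreated preset for {name} is uncalibrated: only the mean fold "
            "change is known, not the untreated per-cell distribution",
            UserWarning,
            stacklevel=2,
        )
    return SimParams(
        silent_fraction=pi,
        expr_mean=mu,
        dispersion=_PRESET_DISPERSION,
        delta_fraction=m["delta"],
        nmd_multiplier=nmd,
        seed=seed,
    )
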