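"""Agreement statistics between measured and reconstructed contact times.

Bland–Altman analysis summarizes method agreement by the mean difference
(bias), the limits of agreement bias ± 1.96·SD of the differences, and
confidence intervals for each; RMSE and Cohen's d complete the report.
Functions here are unit-agnostic: feed seconds or milliseconds consistently
and the report comes back in the same unit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import InfeasibleReconstructionError, StrideTimings, TimingPair, reconstruct_from_tg
from .surrogate import FeasibilityError, PolynomialSurrogate, predict_tg

__all__ = ["AgreementReport", "bland_altman", "cohens_d", "reconstruct_dataset"]

logger = logging.getLogger(__name__)

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementReport:
    """Bland–Altman agreement between two paired measurement series.

    Differences are defined as ``measured - reconstructed``.  ``rmse_pct``
    uses the mean of the measured series as denominator (informational; the
    convention is not standardized).
    """

    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_bias: tuple[float, float]
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    rmse: float
    rmse_pct: float
    cohens_d: float

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        return d

    def to_json(self, path=None) -> str:
        doc = json.dumps({"schema": 1, **self.to_dict()}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    def summary(self, unit: str = "ms") -> str:
        lines = [
            f"n = {self.n}",
            f"bias (measured - reconstructed): {self.bias:.2f} {unit}"
            f"  95% CI [{self.ci_bias[0]:.2f}, {self.ci_bias[1]:.2f}]",
            f"limits of agreement: [{self.loa_lower:.2f}, {self.loa_upper:.2f}] {unit}",
            f"  lower LoA 95% CI [{self.ci_loa_lower[0]:.2f}, {self.ci_loa_lower[1]:.2f}]",
            f"  upper LoA 95% CI [{self.ci_loa_upper[0]:.2f}, {self.ci_loa_upper[1]:.2f}]",
            f"RMSE: {self.rmse:.2f} {unit} ({self.rmse_pct:.1f}%)",
            f"Cohen's d: {self.cohens_d:.2f}",
        ]
        return "\n".join(lines)


def cohens_d(a, b) -> float:
    """Standardized mean difference (mean(a) - mean(b)) / pooled SD.

    The pooled SD is over the two series themselves (not the paired
    differences), the convention for comparing two measurement sets.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both series need n >= 2")
    na, nb = a.size, b.size
    pooled = float(
        np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    )
    if pooled == 0.0:
        raise ValueError("zero pooled SD; effect size undefined")
    return float((a.mean() - b.mean()) / pooled)


def bland_altman(measured, reconstructed, loa_multiplier: float = LOA_MULTIPLIER) -> AgreementReport:
    """Bland–Altman agreement report for two paired series.

    bias = mean(measured - reconstructed); LoA = bias ± multiplier·SD(diff)
    with the sample SD (ddof=1).  CI of the bias uses ±t(0.975, n-1)·SD/√n;
    each LoA's CI uses the large-sample form ±t(0.975, n-1)·SD·√(3/n).
    """
    m = np.asarray(measured, dtype=float)
    r = np.asarray(reconstructed, dtype=float)
    if m.shape != r.shape or m.ndim != 1:
        raise ValueError("measured and reconstructed must be 1-D arrays of equal length")
    n = m.size
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    diff = m - r
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    loa_lo = bias - loa_multiplier * sd
    loa_hi = bias + loa_multiplier * sd
    tq = float(stats.t.ppf(0.975, n - 1))
    half_bias = tq * sd / np.sqrt(n)
    half_loa = tq * sd * np.sqrt(3.0 / n)
    rmse = float(np.sqrt(np.mean(diff**2)))
    mean_measured = float(m.mean())
    rmse_pct = 100.0 * rmse / mean_measured if mean_measured != 0 else float("nan")
    try:
        d = cohens_d(m, r)
    except ValueError:
        d = 0.0 if bias == 0.0 else float("nan")
    return AgreementReport(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_lower=loa_lo,
        loa_upper=loa_hi,
        ci_bias=(bias - half_bias, bias + half_bias),
        ci_loa_lower=(loa_lo - half_loa, loa_lo + half_loa),
        ci_loa_upper=(loa_hi - half_loa, loa_hi + half_loa),
        rmse=rmse,
        rmse_pct=rmse_pct,
        cohens_d=d,
    )


def reconstruct_dataset(
    model: PolynomialSurrogate, pairs: list[TimingPair]
) -> tuple[list[StrideTimings], list[int]]:
    """Reconstruct full stride timings for each pair via the surrogate.

    Each pair is mapped through ``predict_tg`` then ``reconstruct_from_tg``.
    Pairs in the infeasible region (or whose predicted t_g would imply a
    negative flight time) are skipped and logged; their indices are returned
    alongside the reconstructions.
    """
    out: list[StrideTimings] = []
    skipped: list[int] = []
    for idx, pair in enumerate(pairs):
        try:
            tg = predict_tg(model, pair)
            out.append(reconstruct_from_tg(pair, max(tg, 0.0)))
        except (FeasibilityError, InfeasibleReconstructionError) as exc:
            logger.warning("row %d skipped: %s", idx, exc)
            skipped.append(idx)
    return out, skipped


def bland_altman_plot(measured, reconstructed, path, unit: str = "ms"):
    """Scatter of pair means vs differences with bias and LoA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report = bland_altman(measured, reconstructed)
    m = np.asarray(measured, dtype=float)
    r = np.asarray(reconstructed, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter((m + r) / 2, m - r, s=12, alpha=0.6)
    for yv, style in ((report.bias, "-"), (report.loa_lower, "--"), (report.loa_upper, "--")):
        ax.axhline(yv, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel(f"mean of methods ({unit})")
    ax.set_ylabel(f"measured - reconstructed ({unit})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return report
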