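"""Inferential layer: 3x2 repeated-measures ANOVA with partial eta squared,
JZS Bayes-factor t-tests (one- and two-sided), evidence labeling, and the
sequential Bayesian stopping rule.

The default Bayes factor uses a Cauchy(0, r) prior on the standardized
effect size with r = sqrt(2)/2, marginalized by adaptive quadrature over
the noncentral-t likelihood; one-sided variants truncate the prior to the
hypothesized direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "BayesResult",
    "StoppingDecision",
    "rm_anova_3x2",
    "partial_eta_sq",
    "jzs_bf_ttest",
    "label_bf",
    "sequential_stop",
    "planned_comparisons",
]


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    p: float
    eta_p2: float


@dataclass(frozen=True)
class BayesResult:
    bf10: float
    error_pct: float
    sidedness: str
    prior_scale: float
    t: float
    n: int

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


@dataclass(frozen=True)
class StoppingDecision:
    n: int
    bf10: float
    decision: str  # "stop" | "continue"


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Partial eta squared: F*df1 / (F*df1 + df2)."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise ValueError("need F >= 0 and dfs >= 1")
    return F * df1 / (F * df1 + df2)


def rm_anova_3x2(table: pd.DataFrame, dv: str = "amplitude_uv") -> list[AnovaResult]:
    """Two-way fully-within ANOVA: stimulus type (3) x consciousness (2).

    ``table`` is long format with columns participant_id, stim_type,
    awareness and the dependent variable.  Requires a complete balanced
    table (one value per participant per cell).  Degrees of freedom are
    uncorrected (no sphericity correction), matching conventional reporting
    for this design: (2, 2(n-1)) for stimulus type and the interaction,
    (1, n-1) for consciousness.
    """
    import pingouin as pg

    required = {"participant_id", "stim_type", "awareness", dv}
    if not required <= set(table.columns):
        raise ValueError(f"need columns {sorted(required)}")
    n = table["participant_id"].nunique()
    if n < 3:
        raise ValueError("need at least 3 participants")
    counts = table.groupby(["participant_id", "stim_type", "awareness"])[dv].count()
    if (counts != 1).any() or len(counts) != n * 6:
        raise ValueError("table must be complete and balanced: one value per cell")
    aov = pg.rm_anova(
        data=table,
        dv=dv,
        within=["stim_type", "awareness"],
        subject="participant_id",
        detailed=True,
    )
    name_map = {
        "stim_type": "stim_type",
        "awareness": "consciousness",
        "stim_type * awareness": "interaction",
    }
    out = []
    for _, row in aov.iterrows():
        eff = name_map.get(row["Source"])
        if eff is None:
            continue
        F, p = float(row["F"]), float(row["p_unc"])
        if not np.isfinite(F):
            # degenerate 0/0 case: no effect variance and no error variance
            F, p = 0.0, 1.0
        df1, df2 = int(row["ddof1"]), int(row["ddof2"])
        out.append(
            AnovaResult(
                effect=eff,
                F=F,
                df1=df1,
                df2=df2,
                p=p,
                eta_p2=partial_eta_sq(F, df1, df2),
            )
        )
    return out


# --------------------------------------------------------------------------
# JZS Bayes factors
# --------------------------------------------------------------------------

def _jzs_marginal(t: float, n_eff: float, df: float, r: float, lo: float, hi: float,
                  prior_mass: float) -> tuple[float, float]:
    """Integral of the t-likelihood over the (possibly truncated) Cauchy
    prior, computed adaptively after the substitution delta = r*tan(phi)
    that maps the real line to a finite interval."""

    def integrand(phi: float) -> float:
        delta = r * np.tan(phi)
        with warnings.catch_warnings():
            # nct.pdf underflows noisily at extreme noncentrality
            warnings.simplefilter("ignore", RuntimeWarning)
            val = sps.nct.pdf(t, df, delta * np.sqrt(n_eff)) * sps.cauchy.pdf(delta, 0.0, r)
        val *= r / np.cos(phi) ** 2  # Jacobian
        return 0.0 if not np.isfinite(val) else val

    phi_lo = -np.pi / 2 if lo == -np.inf else np.arctan(lo / r)
    phi_hi = np.pi / 2 if hi == np.inf else np.arctan(hi / r)
    # the likelihood peaks near delta = t/sqrt(n_eff); give quad the hint
    peak = np.arctan(t / np.sqrt(n_eff) / r)
    points = [p for p in (peak, 0.0) if phi_lo < p < phi_hi]
    val, err = integrate.quad(
        integrand, phi_lo, phi_hi, points=points or None,
        epsabs=0.0, epsrel=1e-10, limit=300,
    )
    return val / prior_mass, err / prior_mass


def jzs_bf_ttest(
    x,
    y=None,
    paired: bool = False,
    sidedness: str = "two",
    r: float = np.sqrt(2) / 2,
) -> BayesResult:
    """Default (JZS) Bayes factor for one-sample, paired, or two-sample t
    designs.

    ``sidedness`` is "two", "greater" (effect > 0 under H1) or "less".
    One-sided priors are the Cauchy truncated to the hypothesized
    half-line.  The reported error is the quadrature error relative to the
    Bayes factor, in percent.
    """
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
    if sidedness not in ("two", "greater", "less"):
        raise ValueError("sidedness must be 'two', 'greater' or 'less'")

    if y is None or paired:
        d = x if y is None else x - y
        if d.size < 2:
            raise ValueError("need n >= 2")
        if d.std(ddof=1) == 0:
            raise ValueError("zero variance")
        n = d.size
        t = float(d.mean() / (d.std(ddof=1) / np.sqrt(n)))
        n_eff = float(n)
        df = n - 1
    else:
        if x.size < 2 or y.size < 2:
            raise ValueError("need n >= 2 per group")
        t = float(sps.ttest_ind(x, y).statistic)
        n_eff = x.size * y.size / (x.size + y.size)
        df = x.size + y.size - 2
        n = x.size + y.size

    if sidedness == "two":
        lo, hi, mass = -np.inf, np.inf, 1.0
    elif sidedness == "greater":
        lo, hi, mass = 0.0, np.inf, 0.5
    else:
        lo, hi, mass = -np.inf, 0.0, 0.5

    m1, err = _jzs_marginal(t, n_eff, df, r, lo, hi, mass)
    m0 = sps.t.pdf(t, df)
    bf10 = m1 / m0
    return BayesResult(
        bf10=float(bf10),
        error_pct=float(100.0 * err / max(m1, np.finfo(float).tiny)),
        sidedness=sidedness,
        prior_scale=r,
        t=t,
        n=n,
    )


_BF_LABELS = (
    (100.0, "extreme"),
    (30.0, "very strong"),
    (10.0, "strong"),
    (3.0, "moderate"),
    (1.0, "anecdotal"),
)


def label_bf(bf10: float) -> str:
    """Evidence-category label on the conventional Bayes-factor scale,
    mirrored below 1 for evidence of absence (e.g. 'moderate evidence for
    the absence' at bf10 = 1/5)."""
    if bf10 <= 0:
        raise ValueError("bf10 must be positive")
    if bf10 == 1.0:
        return "no evidence"
    value = bf10 if bf10 > 1 else 1.0 / bf10
    for cut, name in _BF_LABELS:
        if value > cut:
            label = name
            break
    else:
        label = "anecdotal"
    side = "for the presence" if bf10 > 1 else "for the absence"
    return f"{label} evidence {side}"


def sequential_stop(
    n: int,
    bf10: float,
    min_n: int = 40,
    upper: float = 3.0,
    lower: float = 1.0 / 3.0,
) -> StoppingDecision:
    """Sequential Bayesian sampling rule: stop once at least ``min_n``
    participants are collected and the monitored BF shows at least moderate
    evidence either way (bf10 > 3 or bf10 < 1/3)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    stop = n >= min_n and (bf10 > upper or bf10 < lower)
    return StoppingDecision(n=n, bf10=bf10, decision="stop" if stop else "continue")


# --------------------------------------------------------------------------
# planned comparisons
# --------------------------------------------------------------------------

# (component, awareness, contrast, sidedness); "greater" means the first-
# listed condition is hypothesized to have the higher signed amplitude for
# the P1 and the more negative amplitude for the N170 (handled below).
PLANNED = [
    ("P1", "conscious", ("face", "blank"), "greater"),
    ("P1", "conscious", ("scramble", "blank"), "greater"),
    ("P1", "conscious", ("face", "scramble"), "two"),
    ("P1", "nonconscious", ("face", "blank"), "greater"),
    ("P1", "nonconscious", ("scramble", "blank"), "greater"),
    ("P1", "nonconscious", ("face", "scramble"), "two"),
    ("N170", "conscious", ("face", "blank"), "less"),
    ("N170", "conscious", ("face", "scramble"), "less"),
    ("N170", "conscious", ("scramble", "blank"), "two"),
    ("N170", "nonconscious", ("face", "blank"), "less"),
    ("N170", "nonconscious", ("face", "scramble"), "less"),
    ("N170", "nonconscious", ("scramble", "blank"), "two"),
]


def planned_comparisons(table: pd.DataFrame, r: float = np.sqrt(2) / 2) -> pd.DataFrame:
    """Paired Bayesian t-tests for the preregistered-style contrasts.

    One-sided where the direction is hypothesized (P1: contrast-carrying
    stimuli above blanks; N170: faces more negative than controls),
    two-sided where the null is predicted (face vs scramble P1,
    scramble vs blank N170).
    """
    wide = table.pivot_table(
        index="participant_id",
        columns=["component", "awareness", "stim_type"],
        values="amplitude_uv",
    )
    rows = []
    for comp, aw, (a, b), side in PLANNED:
        da = wide[(comp, aw, a)]
        db = wide[(comp, aw, b)]
        res = jzs_bf_ttest(da.to_numpy(), db.to_numpy(), paired=True, sidedness=side, r=r)
        rows.append(
            {
                "component": comp,
                "awareness": aw,
                "contrast": f"{a} - {b}",
                "sidedness": side,
                "t": res.t,
                "n": res.n,
                "bf10": res.bf10,
                "bf01": res.bf01,
                "error_pct": res.error_pct,
                "label": label_bf(res.bf10),
            }
        )
    return pd.DataFrame(rows)
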