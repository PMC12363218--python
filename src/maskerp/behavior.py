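"""Behavioral analysis: PAS dichotomization, signal-detection measures,
extreme-bias exclusion, one-sample tests, FDR control.

The dichotomization is deliberately asymmetric across ISI conditions: under
immediate masking (ISI 0) detecting *anything* beyond the mask counts as a
"yes" (PAS > 1), giving a maximally conservative definition of unawareness;
at ISI 200 ms only perceived face features count (PAS >= 3), so d' reflects
conscious face-vs-control discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "dichotomize",
    "correct_rate",
    "sdt_measures",
    "flag_extreme_bias",
    "one_sample_t",
    "cohen_d_from_t",
    "fdr_bh",
    "participant_sdt",
    "analyze_behavior",
    "TTestResult",
]


def dichotomize(pas: int | np.ndarray, isi_ms: int | np.ndarray) -> np.ndarray:
    """Map PAS ratings to yes(True)/no(False) responses.

    ISI 0: PAS = 1 -> no, PAS > 1 -> yes.  ISI 200: PAS <= 2 -> no,
    PAS >= 3 -> yes.
    """
    pas = np.asarray(pas)
    isi = np.asarray(isi_ms)
    if np.any((pas < 1) | (pas > 4)):
        raise ValueError("PAS ratings must lie in 1..4")
    if not np.all(np.isin(isi, (0, 200))):
        raise ValueError("isi_ms must be 0 or 200")
    return np.where(isi == 0, pas > 1, pas >= 3)


def correct_rate(k_yes: int, n: int) -> float:
    """Response rate with extreme-rate replacement: 0 -> 0.5/n and
    n -> (n-0.5)/n (e.g. 0.3125% and 99.6875% at n = 160); interior counts
    are returned untouched as k/n."""
    if n < 1 or not 0 <= k_yes <= n:
        raise ValueError("need 0 <= k_yes <= n, n >= 1")
    if k_yes == 0:
        return 0.5 / n
    if k_yes == n:
        return (n - 0.5) / n
    return k_yes / n


def sdt_measures(hit_rate: float, fa_rate: float) -> tuple[float, float]:
    """Equal-variance SDT: d' = z(H) - z(F), c = -(z(H) + z(F)) / 2.

    Rates of exactly 0 or 1 are rejected; apply :func:`correct_rate` first.
    """
    for r in (hit_rate, fa_rate):
        if not 0 < r < 1:
            raise ValueError("rates must lie strictly inside (0, 1)")
    zh, zf = sps.norm.ppf(hit_rate), sps.norm.ppf(fa_rate)
    return zh - zf, -(zh + zf) / 2


def flag_extreme_bias(
    c_values: np.ndarray, threshold: float = 2.5
) -> tuple[np.ndarray, np.ndarray]:
    """Exclude participants whose criterion, z-standardized across
    participants (sample SD), exceeds ``threshold`` in magnitude.

    Returns ``(keep_mask, z_c)``.  With zero between-participant SD all
    participants are retained.
    """
    c = np.asarray(c_values, dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 participants to standardize")
    sd = c.std(ddof=1)
    if sd == 0:
        import warnings

        warnings.warn("zero criterion SD across participants; none excluded")
        z = np.zeros_like(c)
    else:
        z = (c - c.mean()) / sd
    return np.abs(z) <= threshold, z


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    cohen_d: float
    mean: float


def one_sample_t(values: np.ndarray, mu0: float = 0.0) -> TTestResult:
    """One-sample t-test with Cohen's d = (mean - mu0)/SD = t/sqrt(n)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance")
    res = sps.ttest_1samp(x, popmean=mu0)
    return TTestResult(
        t=float(res.statistic),
        df=x.size - 1,
        p=float(res.pvalue),
        cohen_d=float(res.statistic) / np.sqrt(x.size),
        mean=float(x.mean()),
    )


def cohen_d_from_t(t: float, n: int) -> float:
    """One-sample/paired-design effect size implied by a t value."""
    return t / np.sqrt(n)


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up flags and the largest rejected p value
    (0.0 when nothing is rejected)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return reject, threshold


def participant_sdt(
    trials: pd.DataFrame, signal: str = "face", noise: str = "blank"
) -> pd.DataFrame:
    """Per-participant, per-ISI SDT measures from a PAS trial table.

    Hits are "yes" responses to ``signal`` targets, false alarms "yes"
    responses to ``noise`` targets, after the ISI-specific dichotomization.
    Columns: participant_id, isi_ms, n_signal, n_noise, hit_rate, fa_rate,
    d_prime, c.
    """
    required = {"participant_id", "stim_type", "isi_ms", "pas"}
    if not required <= set(trials.columns):
        raise ValueError(f"trial table must have columns {sorted(required)}")
    rows = []
    yes = dichotomize(trials["pas"].to_numpy(), trials["isi_ms"].to_numpy())
    t = trials.assign(yes=yes)
    for (pid, isi), grp in t.groupby(["participant_id", "isi_ms"], sort=True):
        sig = grp[grp["stim_type"] == signal]
        noi = grp[grp["stim_type"] == noise]
        if len(sig) == 0 or len(noi) == 0:
            continue
        hr = correct_rate(int(sig["yes"].sum()), len(sig))
        fr = correct_rate(int(noi["yes"].sum()), len(noi))
        d, c = sdt_measures(hr, fr)
        rows.append(
            {
                "participant_id": pid,
                "isi_ms": isi,
                "n_signal": len(sig),
                "n_noise": len(noi),
                "hit_rate": hr,
                "fa_rate": fr,
                "d_prime": d,
                "c": c,
            }
        )
    return pd.DataFrame(rows)


def analyze_behavior(
    trials: pd.DataFrame,
    signal: str = "face",
    q: float = 0.05,
    z_threshold: float = 2.5,
) -> dict:
    """Full behavioral stage: SDT per participant/ISI, extreme-bias
    exclusion on the cross-condition mean criterion, group one-sample
    t-tests of d' and c per ISI with BH-FDR over that four-test family.

    Returns a dict with ``sdt`` (per-participant table incl. z_c and
    retained flag), ``excluded`` (ids), and ``group_tests``.
    """
    sdt = participant_sdt(trials, signal=signal)
    mean_c = sdt.groupby("participant_id")["c"].mean()  # unweighted across ISI
    keep, z = flag_extreme_bias(mean_c.to_numpy(), threshold=z_threshold)
    zmap = dict(zip(mean_c.index, z))
    keepmap = dict(zip(mean_c.index, keep))
    sdt["z_c"] = sdt["participant_id"].map(zmap)
    sdt["retained"] = sdt["participant_id"].map(keepmap)
    excluded = sorted(pid for pid, k in keepmap.items() if not k)

    tests = []
    retained = sdt[sdt["retained"]]
    for isi in sorted(retained["isi_ms"].unique()):
        sub = retained[retained["isi_ms"] == isi]
        for measure in ("d_prime", "c"):
            r = one_sample_t(sub[measure].to_numpy())
            tests.append(
                {
                    "measure": measure,
                    "isi_ms": isi,
                    "n": len(sub),
                    "mean": r.mean,
                    "t": r.t,
                    "df": r.df,
                    "p": r.p,
                    "cohen_d": r.cohen_d,
                }
            )
    group = pd.DataFrame(tests)
    if len(group):
        group["significant_fdr"], _ = fdr_bh(group["p"].to_numpy(), q=q)
    return {"sdt": sdt, "excluded": excluded, "group_tests": group}
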