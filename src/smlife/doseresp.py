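"""Hill dose-response fits and promoter-comparison metrics.

Titration curves are fit with the 4-parameter Hill equation

    r(d) = leak + (max - leak) * d^n / (K^n + d^n)

where ``leak`` is expression at zero dose, ``max`` the saturating
response, ``K`` the half-maximal dose and ``n`` the Hill coefficient
(cooperativity; n near 1 means non-cooperative induction).  From the fit,
promoter characteristics follow: dynamic range (max/leak), leakiness
(leak as a percentage of a reference promoter's maximum) and the Hill
coefficient with a parametric-bootstrap 95% CI.  A fit whose half-maximal
dose exceeds the largest tested dose is flagged "could not saturate".

Doses are fitted on a linear scale with log-spaced multi-starts for K, so
dose ranges spanning orders of magnitude are handled robustly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

_N_MAX = 25.0


def hill(d, leak, max_response, k_half, n_hill):
    """Hill response function, safe at d = 0."""
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dn = np.where(d > 0, d**n_hill, 0.0)
    return leak + (max_response - leak) * dn / (k_half**n_hill + dn)


class HillModel:
    """Hill dose-response model built from tidy (dose, response) data."""

    def __init__(self, doses, responses):
        doses = np.asarray(doses, dtype=float)
        responses = np.asarray(responses, dtype=float)
        if doses.shape != responses.shape or doses.ndim != 1:
            raise ValueError("doses and responses must be matching 1-D arrays")
        if np.any(doses < 0):
            raise ValueError("doses must be non-negative")
        if len(np.unique(doses)) < 4:
            raise ValueError("need at least 4 distinct doses")
        if np.allclose(responses, responses[0]):
            raise ValueError("degenerate fit: all responses equal")
        self.doses = doses
        self.responses = responses

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, dose_col: str = "dose", response_col: str = "response"
    ) -> "HillModel":
        return cls(df[dose_col].to_numpy(), df[response_col].to_numpy())

    def _single_fit(self, p0, bounds):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                hill, self.doses, self.responses, p0=p0, bounds=bounds, maxfev=20_000
            )
        rss = float(np.sum((hill(self.doses, *popt) - self.responses) ** 2))
        return popt, rss

    def fit(self, n_boot: int = 2000, seed: int = 0, alpha: float = 0.05) -> "HillResults":
        """Least-squares Hill fit with multi-start and a bootstrap CI on n.

        The (K, n) starting grid spans the positive dose range
        log-uniformly crossed with n in {0.5, 1, 2, 4}; the best
        residual-sum-of-squares fit wins.  The CI on the Hill coefficient
        is a parametric bootstrap of multiplicative residuals: the
        response/fit ratios are resampled onto the fitted curve and the
        model refit (``n_boot`` times, seeded).  Fluorescence titration
        noise is proportional to signal, so resampling ratios rather than
        additive residuals preserves the heteroscedasticity; additive
        resampling undercovers markedly on such data.
        """
        d, r = self.doses, self.responses
        pos = d[d > 0]
        r_lo, r_hi = float(r.min()), float(r.max())
        span = max(r_hi - r_lo, 1e-12)
        bounds = (
            [0.0, 0.0, pos.min() * 1e-3, 1e-2],
            [r_hi * 2 + 1e-9, (r_hi + span) * 10 + 1e-9, pos.max() * 1e3, _N_MAX],
        )
        k_grid = np.geomspace(pos.min(), pos.max(), 6)
        best = None
        for k0 in k_grid:
            for n0 in (0.5, 1.0, 2.0, 4.0):
                p0 = [max(r_lo, 1e-9), r_hi, k0, n0]
                try:
                    popt, rss = self._single_fit(p0, bounds)
                except RuntimeError:
                    continue
                if best is None or rss < best[1]:
                    best = (popt, rss)
        if best is None:
            raise RuntimeError("Hill fit failed from every starting point")
        popt, rss = best
        leak, max_response, k_half, n_hill = (float(v) for v in popt)
        saturated = k_half <= d.max()

        rng = np.random.default_rng(seed)
        yhat = hill(d, *popt)
        ratios = r / np.maximum(yhat, 1e-12)
        boot_n = []
        for _ in range(n_boot):
            y_star = yhat * rng.choice(ratios, size=ratios.size, replace=True)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p_star, _ = curve_fit(
                        hill, d, y_star, p0=popt, bounds=bounds, maxfev=5_000
                    )
                boot_n.append(p_star[3])
            except RuntimeError:
                continue
        if boot_n:
            ci = tuple(float(v) for v in np.quantile(boot_n, [alpha / 2, 1 - alpha / 2]))
            ci = (min(ci[0], n_hill), max(ci[1], n_hill))
        else:
            ci = (n_hill, n_hill)
        return HillResults(
            model=self,
            leak=leak,
            max_response=max_response,
            k_half=k_half,
            n_hill=n_hill,
            ci95_n_hill=ci,
            rss=rss,
            saturated=bool(saturated),
            n_obs=len(d),
            seed=int(seed),
        )


@dataclass
class HillResults:
    """Fitted Hill curve with derived promoter metrics."""

    model: HillModel
    leak: float
    max_response: float
    k_half: float
    n_hill: float
    ci95_n_hill: tuple[float, float]
    rss: float
    saturated: bool
    n_obs: int
    seed: int = 0

    def predict(self, doses) -> np.ndarray:
        return hill(doses, self.leak, self.max_response, self.k_half, self.n_hill)

    @property
    def dynamic_range(self) -> float:
        return self.max_response / self.leak if self.leak > 0 else float("inf")

    def metrics(self, reference_max: float) -> "PromoterMetrics":
        return promoter_metrics(self, reference_max)

    def summary(self) -> str:
        sat = "yes" if self.saturated else "COULD NOT SATURATE (k_half beyond max dose)"
        return "\n".join(
            [
                "Hill dose-response fit",
                "=" * 42,
                f"  leak (zero-dose)     {self.leak:12.4g}",
                f"  max (saturating)     {self.max_response:12.4g}",
                f"  k_half               {self.k_half:12.4g}",
                f"  Hill coefficient n   {self.n_hill:12.4g}",
                f"  95% CI on n          [{self.ci95_n_hill[0]:.3g}, {self.ci95_n_hill[1]:.3g}]",
                f"  dynamic range        {self.dynamic_range:12.4g}",
                f"  RSS                  {self.rss:12.4g}   (n = {self.n_obs})",
                f"  saturated            {sat}",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "leak": self.leak,
            "max": self.max_response,
            "k_half": self.k_half,
            "n_hill": self.n_hill,
            "n_ci_low": self.ci95_n_hill[0],
            "n_ci_high": self.ci95_n_hill[1],
            "rss": self.rss,
            "dynamic_range": self.dynamic_range,
            "saturated": self.saturated,
        }

    def plot(self, ax=None):
        """Data points and the fitted sigmoid on a symlog dose axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d, r = self.model.doses, self.model.responses
        ax.plot(d, r, "o", alpha=0.6, label="data")
        pos = d[d > 0]
        grid = np.concatenate([[0.0], np.geomspace(pos.min() / 3, pos.max() * 1.5, 200)])
        ax.plot(grid, self.predict(grid), "k-", label="Hill fit")
        ax.set_xscale("symlog", linthresh=pos.min() / 2)
        ax.set_xlabel("inducer dose")
        ax.set_ylabel("response")
        ax.legend()
        return ax


@dataclass
class PromoterMetrics:
    """Promoter-comparison metrics derived from a Hill fit."""

    dynamic_range: float
    leakiness_pct: float  # fitted leak as % of the reference promoter's max
    fold_induction: float  # max observed / min observed response
    leak_is_zero: bool = False


def promoter_metrics(fit: HillResults, reference_max: float) -> PromoterMetrics:
    """Dynamic range, leakiness (% of reference max) and fold induction.

    Dynamic range is fitted max over fitted leak (infinite, flagged, for a
    zero-leak construct); leakiness is fitted leak as a percentage of
    ``reference_max``; fold induction is the ratio of extreme observed
    responses.
    """
    if reference_max <= 0:
        raise ValueError("reference_max must be > 0")
    leak_zero = fit.leak <= 0
    dr = float("inf") if leak_zero else fit.max_response / fit.leak
    resp = fit.model.responses
    fold = float(resp.max() / resp.min()) if resp.min() > 0 else float("inf")
    return PromoterMetrics(
        dynamic_range=float(dr),
        leakiness_pct=float(100.0 * fit.leak / reference_max),
        fold_induction=fold,
        leak_is_zero=leak_zero,
    )


def grid_summary(
    table: pd.DataFrame,
    iptg_col: str = "iptg",
    nsaa_col: str = "nsaa",
    response_col: str = "response",
    n_boot: int = 200,
    seed: int = 0,
) -> dict:
    """Summarize a 2-D (transcriptional x translational) induction grid.

    Fits the nsAA dose axis at each IPTG level (where at least 4 distinct
    nsAA doses exist) and reports overall fold induction — the ratio of the
    largest to the smallest grid cell — with the argmax/argmin cells.
    Missing cells are excluded from the extrema with a warning.
    """
    df = table[[iptg_col, nsaa_col, response_col]].copy()
    n_missing = df[response_col].isna().sum()
    if n_missing:
        warnings.warn(f"{n_missing} missing grid cells excluded from extrema")
        df = df.dropna(subset=[response_col])
    if np.any(df[response_col] <= 0):
        raise ValueError("non-positive response in grid: fold induction undefined")
    fits: dict[float, HillResults] = {}
    for level, sub in df.groupby(iptg_col):
        if sub[nsaa_col].nunique() < 4:
            continue
        try:
            fits[float(level)] = HillModel(
                sub[nsaa_col].to_numpy(), sub[response_col].to_numpy()
            ).fit(n_boot=n_boot, seed=seed)
        except (ValueError, RuntimeError):
            continue
    i_max = df[response_col].idxmax()
    i_min = df[response_col].idxmin()
    return {
        "fits_by_iptg": fits,
        "fold_induction": float(df.loc[i_max, response_col] / df.loc[i_min, response_col]),
        "argmax": (float(df.loc[i_max, iptg_col]), float(df.loc[i_max, nsaa_col])),
        "argmin": (float(df.loc[i_min, iptg_col]), float(df.loc[i_min, nsaa_col])),
    }


def fits_to_frame(fits: dict[str, HillResults], reference_max: float | None = None) -> pd.DataFrame:
    """Tabulate named fits as the promoter-characteristics table."""
    rows = []
    ref = reference_max
    if ref is None and fits:
        ref = max(f.max_response for f in fits.values())
    for name, f in fits.items():
        m = promoter_metrics(f, ref)
        rows.append(
            {
                "promoter": name,
                "leak": f.leak,
                "max": f.max_response,
                "k_half": f.k_half,
                "n_hill": f.n_hill,
                "n_ci_low": f.ci95_n_hill[0],
                "n_ci_high": f.ci95_n_hill[1],
                "dynamic_range": m.dynamic_range,
                "leakiness_pct": m.leakiness_pct,
                "saturated": f.saturated,
            }
        )
    return pd.DataFrame(rows)
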