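"""Laisk estimation of ci* and Rd by slope–intercept regression.

Low-CO2 A–ci curves measured at several sub-saturating irradiances are
each fitted with an ordinary-least-squares line A = a_p + b_p · ci.  If
the lines shared an exact common intersection (ci*, -Rd), every line
would satisfy a_p = -Rd - ci* · b_p, i.e. the intercepts would be an
exact linear function of the slopes.  The slope–intercept method
therefore regresses intercepts on slopes,

    a = α + β b   with   ci* = -β,  Rd = -α,

which uses all lines symmetrically and degrades gracefully when noise
(or FvCB curvature at low CO2) perturbs the common intersection.

``LaiskModel`` follows the Model/Results convention: build it from a
family of sub-curves (or a long-format DataFrame), call :meth:`fit`, and
read the estimates off the returned :class:`LaiskResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .records import ResponseCurve

__all__ = ["DegenerateDesignError", "LaiskModel", "LaiskResults", "pool_laisk"]

_SLOPE_SPREAD_TOL = 1e-12


class DegenerateDesignError(ValueError):
    """Fewer than two usable lines, or slopes too collinear to intersect."""


class LaiskModel:
    """Slope–intercept Laisk regression over a family of low-CO2 curves.

    Parameters
    ----------
    family : list of ResponseCurve
        Sub-curves measured at distinct PAR levels; each needs >= 3
        (ci, A) points.
    """

    def __init__(self, family: list[ResponseCurve]):
        if len(family) < 2:
            raise DegenerateDesignError("need >= 2 sub-curves at distinct PAR")
        pars = []
        for curve in family:
            if len(curve.records) < 3:
                raise DegenerateDesignError("each sub-curve needs >= 3 points")
            pars.append(curve.records[0].PAR)
        if len(set(pars)) < len(pars):
            raise DegenerateDesignError("PAR levels must be distinct")
        self.family = family

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        curve_col: str = "curve_id",
        par_col: str = "PAR",
        ci_col: str = "ci",
        a_col: str = "A",
    ) -> "LaiskModel":
        """Build from a long table of (curve_id, PAR, ci, A) rows."""
        from .records import GasExchangeRecord

        family = []
        for _, sub in df.groupby(curve_col, sort=False):
            records = [
                GasExchangeRecord(
                    A=float(r[a_col]), gs_w=0.0, ci=float(r[ci_col]),
                    ca=float(r[ci_col]), PAR=float(r[par_col]),
                )
                for _, r in sub.iterrows()
            ]
            family.append(ResponseCurve(curve_type="laisk", records=records))
        return cls(family)

    def fit(self) -> "LaiskResults":
        """Fit per-line OLS then the intercepts-on-slopes meta regression."""
        lines = []
        for curve in self.family:
            ci = np.array([r.ci for r in curve.records], dtype=float)
            A = np.array([r.A for r in curve.records], dtype=float)
            X = sm.add_constant(ci)
            res = sm.OLS(A, X).fit()
            intercept, slope = res.params
            lines.append(
                {
                    "PAR": curve.records[0].PAR,
                    "slope": slope,
                    "intercept": intercept,
                    "r2": res.rsquared,
                    "n": len(ci),
                }
            )
        lines_df = pd.DataFrame(lines)
        slopes = lines_df["slope"].to_numpy()
        if np.ptp(slopes) < _SLOPE_SPREAD_TOL:
            raise DegenerateDesignError(
                "slope spread below 1e-12: lines cannot locate an intersection"
            )
        X = sm.add_constant(slopes)
        meta = sm.OLS(lines_df["intercept"].to_numpy(), X).fit()
        alpha, beta = (float(v) for v in meta.params)
        rd = -alpha
        return LaiskResults(
            ci_star=float(-beta),
            Rd=rd,
            lines=lines_df,
            meta_params=(alpha, beta),
            meta_bse=tuple(float(v) for v in meta.bse),
            n_lines=int(len(lines_df)),
            rd_negative=bool(rd < 0),
        )


@dataclass
class LaiskResults:
    """Estimates and diagnostics from :meth:`LaiskModel.fit`.

    ``ci_star`` is the apparent photorespiratory compensation point
    (µmol mol⁻¹) and ``Rd`` the day respiration (µmol m⁻² s⁻¹).
    Negative Rd is reported as-is with ``rd_negative`` set.
    """

    ci_star: float
    Rd: float
    lines: pd.DataFrame
    meta_params: tuple[float, float]
    meta_bse: tuple[float, float]
    n_lines: int
    rd_negative: bool

    def summary(self) -> str:
        alpha, beta = self.meta_params
        se_a, se_b = self.meta_bse
        out = [
            "Laisk slope-intercept regression",
            "=" * 40,
            f"ci*  : {self.ci_star:10.4f} umol mol-1  (SE {se_b:.4f})",
            f"Rd   : {self.Rd:10.4f} umol m-2 s-1  (SE {se_a:.4f})",
            f"lines: {self.n_lines}",
        ]
        if self.rd_negative:
            out.append("flag : negative Rd estimate")
        out.append("-" * 40)
        for _, ln in self.lines.iterrows():
            out.append(
                f"PAR {ln['PAR']:7.1f}  slope {ln['slope']:+.5f}  "
                f"intercept {ln['intercept']:+.4f}  r2 {ln['r2']:.5f}  n {int(ln['n'])}"
            )
        return "\n".join(out)

    def to_dict(self) -> dict:
        return {
            "ci_star": self.ci_star,
            "Rd": self.Rd,
            "n_lines": self.n_lines,
            "rd_negative": self.rd_negative,
            "lines": self.lines.to_dict(orient="records"),
        }

    def plot(self, ax=None, ci_range: tuple[float, float] = (20.0, 160.0)):
        """Diagnostic plot: the fitted per-PAR lines and their intersection."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ci = np.linspace(*ci_range, 50)
        for _, ln in self.lines.iterrows():
            ax.plot(ci, ln["intercept"] + ln["slope"] * ci,
                    label=f"PAR {ln['PAR']:.0f}")
        ax.plot(self.ci_star, -self.Rd, "ko", ms=7,
                label=f"(ci*={self.ci_star:.1f}, -Rd={-self.Rd:.2f})")
        ax.axhline(0.0, color="0.7", lw=0.8)
        ax.set_xlabel("ci (µmol mol$^{-1}$)")
        ax.set_ylabel("A (µmol m$^{-2}$ s$^{-1}$)")
        ax.legend(fontsize=8)
        return ax


def pool_laisk(results: list[LaiskResults]) -> tuple[float, float]:
    """Pool per-plant Laisk fits into global (ci*, Rd) averages.

    Uses an n-weighted mean with each fit weighted by its number of
    lines.  Returns ``(ci_star, Rd)``.
    """
    if not results:
        raise ValueError("no results to pool")
    w = np.array([r.n_lines for r in results], dtype=float)
    ci = np.array([r.ci_star for r in results])
    rd = np.array([r.Rd for r in results])
    return float(np.average(ci, weights=w)), float(np.average(rd, weights=w))
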