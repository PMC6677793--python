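"""Radioligand saturation-binding analysis.

Covers the co-sedimentation readout chain: scintillation counts ->
concentration via specific activity, one-site saturation fit
B(L) = Bmax * L / (Kd + L), stoichiometry per overlap junction, and the
pre- vs post-incubation comparison that distinguishes incorporation during
co-polymerization from binding to preformed filaments.

The model objects follow the statsmodels convention: build a model from
data, ``fit()`` returns a results object carrying estimates, standard
errors and a ``summary()`` table.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    ComparisonError,
    DilutionError,
    FitError,
    ParameterError,
)

#: disintegrations per minute in one millicurie
DPM_PER_MCI = 2.22e9


# ---------------------------------------------------------------------------
# counts <-> concentration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpecificActivity:
    """Radioactivity per mole: mCi/mmol, with a cpm->dpm counting efficiency."""

    value: float  # mCi/mmol
    counting_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ParameterError("specific activity must be positive")
        if not 0 < self.counting_efficiency <= 1:
            raise ParameterError("counting efficiency must be in (0, 1]")


def dpm_per_uM(specific_activity_mci_per_mmol: float, volume_l: float) -> float:
    """dpm produced by 1 uM of labelled compound in the given volume."""
    if specific_activity_mci_per_mmol <= 0 or volume_l <= 0:
        raise ParameterError("specific activity and volume must be positive")
    # 1 uM = 1e-3 mmol/L
    return 1e-3 * volume_l * specific_activity_mci_per_mmol * DPM_PER_MCI


def cpm_to_concentration(
    counts_cpm: float | np.ndarray,
    specific_activity: SpecificActivity | float,
    volume_l: float,
) -> float | np.ndarray:
    """Concentration (uM) of labelled compound from raw counts.

    amount(mmol) = (counts / efficiency) / (SA * 2.22e9 dpm/mCi);
    concentration = amount / volume.  Linear in counts, inverse-linear in
    specific activity.
    """
    sa = specific_activity if isinstance(specific_activity, SpecificActivity) else SpecificActivity(specific_activity)
    counts = np.asarray(counts_cpm, dtype=float)
    if np.any(counts < 0):
        raise ParameterError("counts must be >= 0")
    dpm = counts / sa.counting_efficiency
    mmol = dpm / (sa.value * DPM_PER_MCI)
    conc_uM = mmol / volume_l * 1e3  # mmol/L -> mM -> uM is *1e3
    if np.isscalar(counts_cpm):
        return float(conc_uM)
    return conc_uM


def dilution_to_specific_activity(
    hot_sa_mci_per_mmol: float,
    cold_to_hot_ratio: float | None = None,
    target_mci_per_mmol: float | None = None,
) -> SpecificActivity | float:
    """Specific activity after isotopic dilution with unlabelled compound.

    With ``cold_to_hot_ratio`` given: returns SA_mix = hot / (1 + ratio).
    With ``target_mci_per_mmol`` given instead: inverse mode, returns the
    cold:hot molar ratio required to reach the target.
    """
    if hot_sa_mci_per_mmol <= 0:
        raise ParameterError("hot specific activity must be positive")
    if (cold_to_hot_ratio is None) == (target_mci_per_mmol is None):
        raise ParameterError("give exactly one of cold_to_hot_ratio or target")
    if target_mci_per_mmol is not None:
        if target_mci_per_mmol >= hot_sa_mci_per_mmol:
            raise DilutionError("target specific activity must be below the hot stock")
        return hot_sa_mci_per_mmol / target_mci_per_mmol - 1.0
    if cold_to_hot_ratio < 0:
        raise ParameterError("cold:hot ratio must be >= 0")
    return SpecificActivity(hot_sa_mci_per_mmol / (1.0 + cold_to_hot_ratio))


# ---------------------------------------------------------------------------
# isotherm container
# ---------------------------------------------------------------------------


@dataclass
class Isotherm:
    """Free-ligand vs bound table for one condition.

    ``data`` columns: concentration_uM, bound_uM, and optionally replicate.
    """

    data: pd.DataFrame
    condition: Literal["pre_incubation", "post_incubation"] = "pre_incubation"

    def __post_init__(self) -> None:
        req = {"concentration_uM", "bound_uM"}
        if not req <= set(self.data.columns):
            raise ParameterError(f"isotherm table needs columns {sorted(req)}")
        if (self.data["concentration_uM"] < 0).any():
            raise ParameterError("concentrations must be >= 0")

    @classmethod
    def from_csv(cls, path: str | Path, condition: str | None = None) -> "Isotherm":
        df = pd.read_csv(path)
        if condition is not None and "condition" in df.columns:
            df = df[df["condition"] == condition].reset_index(drop=True)
        cond = condition or (df["condition"].iloc[0] if "condition" in df.columns else "pre_incubation")
        return cls(data=df, condition=cond)

    @property
    def L(self) -> np.ndarray:
        return self.data["concentration_uM"].to_numpy(float)

    @property
    def bound(self) -> np.ndarray:
        return self.data["bound_uM"].to_numpy(float)

    def mean_by_concentration(self) -> pd.DataFrame:
        return (
            self.data.groupby("concentration_uM", as_index=False)["bound_uM"]
            .mean()
            .sort_values("concentration_uM", ignore_index=True)
        )


# ---------------------------------------------------------------------------
# one-site model
# ---------------------------------------------------------------------------


def one_site(L: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    """Specific binding to a single class of sites (free-ligand form)."""
    return bmax * L / (kd + L)


def one_site_depleted(L_total: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    """One-site binding against *total* ligand with depletion correction.

    Solves B^2 - B(Ltot + Bmax + Kd) + Ltot*Bmax = 0 for the physical root.
    """
    s = L_total + bmax + kd
    return 0.5 * (s - np.sqrt(s * s - 4.0 * L_total * bmax))


class OneSiteBindingModel:
    """One-site specific binding, fit by nonlinear least squares.

    Parameters
    ----------
    isotherm : Isotherm or DataFrame
        Free-ligand (or total-ligand, see ``depletion``) vs bound data in uM.
    depletion : bool
        Treat the concentration column as total ligand and fit the
        depletion-corrected form.
    fixed_bmax : float, optional
        Constrain Bmax and fit only Kd.
    """

    def __init__(
        self,
        isotherm: Isotherm | pd.DataFrame,
        depletion: bool = False,
        fixed_bmax: float | None = None,
    ) -> None:
        if isinstance(isotherm, pd.DataFrame):
            isotherm = Isotherm(data=isotherm)
        self.isotherm = isotherm
        self.depletion = depletion
        self.fixed_bmax = fixed_bmax
        if len(np.unique(isotherm.L[isotherm.L > 0])) < 4:
            raise ParameterError("need >=4 distinct non-zero concentrations to fit")

    def fit(self) -> "OneSiteBindingResults":
        L, B = self.isotherm.L, self.isotherm.bound
        if np.all(B <= 0):
            raise FitError("all bound values are <= 0: nothing to fit")
        func = one_site_depleted if self.depletion else one_site
        bmax0 = float(np.max(B))
        kd0 = float(np.median(L))
        try:
            if self.fixed_bmax is not None:
                popt, pcov = curve_fit(
                    lambda x, kd: func(x, self.fixed_bmax, kd),
                    L, B, p0=[kd0], bounds=(1e-12, np.inf), maxfev=20000,
                )
                bmax, kd = self.fixed_bmax, float(popt[0])
                bse = {"bmax": 0.0, "kd": float(np.sqrt(pcov[0, 0]))}
            else:
                popt, pcov = curve_fit(
                    func, L, B, p0=[bmax0, kd0],
                    bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000,
                )
                bmax, kd = map(float, popt)
                errs = np.sqrt(np.diag(pcov))
                bse = {"bmax": float(errs[0]), "kd": float(errs[1])}
        except RuntimeError as exc:
            raise FitError(f"one-site fit did not converge: {exc}") from exc
        resid = B - func(L, bmax, kd)
        ill = bool(np.max(L) < kd)
        if ill:
            warnings.warn(
                "max ligand concentration below the apparent Kd: "
                "fit is ill-conditioned and standard errors are wide",
                stacklevel=2,
            )
        return OneSiteBindingResults(
            model=self,
            kd=kd,
            bmax=bmax,
            bse=bse,
            rss=float(np.sum(resid**2)),
            nobs=len(L),
            ill_conditioned=ill,
        )


@dataclass
class OneSiteBindingResults:
    """Estimates from :class:`OneSiteBindingModel.fit`."""

    model: OneSiteBindingModel
    kd: float
    bmax: float
    bse: dict[str, float]
    rss: float
    nobs: int
    ill_conditioned: bool = False

    def predict(self, L: np.ndarray) -> np.ndarray:
        func = one_site_depleted if self.model.depletion else one_site
        return func(np.asarray(L, float), self.bmax, self.kd)

    def molar_ratio_per_junction(
        self, tpm_dimer_uM: float, junctions_per_dimer: float = 1.0
    ) -> float:
        """Saturation stoichiometry: Bmax per overlap junction."""
        return molar_ratio_per_junction(self.bmax, tpm_dimer_uM, junctions_per_dimer)

    def summary(self) -> str:
        lines = [
            "One-site specific binding: B(L) = Bmax * L / (Kd + L)",
            f"  observations: {self.nobs}"
            + ("  (depletion-corrected, total-ligand form)" if self.model.depletion else ""),
            f"  Kd   = {self.kd:10.4g} uM   (SE {self.bse['kd']:.3g})",
            f"  Bmax = {self.bmax:10.4g}      (SE {self.bse['bmax']:.3g})",
            f"  residual sum of squares = {self.rss:.4g}",
        ]
        if self.ill_conditioned:
            lines.append("  WARNING: concentrations do not reach Kd; estimates unstable")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kd_uM": self.kd,
            "bmax": self.bmax,
            "se_kd": self.bse["kd"],
            "se_bmax": self.bse["bmax"],
            "rss": self.rss,
            "n": self.nobs,
            "ill_conditioned": self.ill_conditioned,
        }


def fit_one_site(
    isotherm: Isotherm | pd.DataFrame,
    depletion: bool = False,
    fixed_bmax: float | None = None,
) -> OneSiteBindingResults:
    """Convenience wrapper: build the model and fit."""
    return OneSiteBindingModel(isotherm, depletion=depletion, fixed_bmax=fixed_bmax).fit()


def molar_ratio_per_junction(
    bound_ligand_uM: float, tpm_dimer_uM: float, junctions_per_dimer: float = 1.0
) -> float:
    """Moles of ligand per overlap junction.

    In a continuous head-to-tail co-polymer each dimer contributes one
    junction, so the default ``junctions_per_dimer`` is 1; finite filaments
    of n dimers have (n-1)/n.
    """
    if tpm_dimer_uM <= 0:
        raise ParameterError("dimer concentration must be positive")
    if not 0 < junctions_per_dimer <= 1:
        raise ParameterError("junctions_per_dimer must be in (0, 1]")
    return bound_ligand_uM / (tpm_dimer_uM * junctions_per_dimer)


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------


@dataclass
class ConditionComparison:
    """Pre- vs post-incubation difference, per shared concentration."""

    table: pd.DataFrame  # concentration_uM, bound_pre, bound_post, difference
    pre_bmax: float
    background_fraction: float
    background_level: bool
    post_exceeds_pre: bool

    def summary(self) -> str:
        flag = (
            f"post-incubation binding is background-level "
            f"(< {self.background_fraction:.0%} of pre-incubation Bmax everywhere)"
            if self.background_level
            else "post-incubation binding is above the background threshold"
        )
        lines = [
            f"Pre- vs post-incubation over {len(self.table)} shared concentrations",
            f"  pre-incubation Bmax = {self.pre_bmax:.4g}",
            f"  mean bound difference (pre - post) = {self.table['difference'].mean():.4g}",
            f"  {flag}",
        ]
        if self.post_exceeds_pre:
            lines.append("  note: post-incubation bound exceeds pre at every concentration")
        return "\n".join(lines)


def compare_conditions(
    pre: Isotherm,
    post: Isotherm,
    background_fraction: float = 0.20,
) -> ConditionComparison:
    """Per-concentration bound difference and background-level flag.

    The flag is set when the post-condition bound stays below
    ``background_fraction`` of the pre-condition Bmax across the shared
    concentration range (incorporation into preformed filaments close to
    background).
    """
    pre_m = pre.mean_by_concentration()
    post_m = post.mean_by_concentration()
    merged = pre_m.merge(post_m, on="concentration_uM", suffixes=("_pre", "_post"))
    if merged.empty:
        raise ComparisonError("conditions share no concentrations")
    merged["difference"] = merged["bound_uM_pre"] - merged["bound_uM_post"]
    bmax = fit_one_site(pre).bmax
    background = bool((merged["bound_uM_post"] < background_fraction * bmax).all())
    exceeds = bool((merged["bound_uM_post"] > merged["bound_uM_pre"]).all())
    return ConditionComparison(
        table=merged.rename(
            columns={"bound_uM_pre": "bound_pre", "bound_uM_post": "bound_post"}
        ),
        pre_bmax=bmax,
        background_fraction=background_fraction,
        background_level=background,
        post_exceeds_pre=exceeds,
    )
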