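"""Model/Results interface for the ROI lesion-deficit analysis.

`LesionDeficitModel` holds the subject-level data (target score, ROI lesion
load, covariates); `fit()` returns a `LesionDeficitResults` carrying the
partial-correlation effect size, its flat-prior credible interval, and a
summary table. The bootstrap reproducibility study hangs off the results
object, since it resamples the fitted cohort around the fitted effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from .config import COVARIATE_COLUMNS, SCORE_COLUMNS
from . import bootstrap as _boot
from .effects import (
    CredibleInterval,
    PartialCorrResult,
    analytic_power,
    credible_interval_r2,
    critical_r2,
    partial_correlation,
    sign_error_probability,
)

__all__ = ["LesionDeficitModel", "LesionDeficitResults", "BootstrapStudyResults"]


class LesionDeficitModel:
    """Partial-correlation model of a behavioural deficit on ROI lesion load.

    Parameters
    ----------
    target : (n,) array_like
        Behavioural score of interest (T-scores).
    lesion_load : (n,) array_like
        Mean fuzzy abnormality over the ROI, one fraction per patient.
    covariates : (n, k) array_like
        Nuisance variables partialled out of both (typically the four other
        behavioural scores and lesion size, k = 5).
    covariate_names : sequence of str, optional

    Examples
    --------
    >>> model = LesionDeficitModel.from_dataframe(cohort, lesion_load=load)
    >>> res = model.fit()
    >>> res.r2, res.credible_interval().lower_r2   # doctest: +SKIP
    """

    def __init__(self, target, lesion_load, covariates, covariate_names=None,
                 target_name="score_repn"):
        self.target = np.asarray(target, dtype=float).ravel()
        self.lesion_load = np.asarray(lesion_load, dtype=float).ravel()
        self.covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if self.covariates.shape[0] != self.target.size:
            self.covariates = self.covariates.T
        self.covariate_names = (
            list(covariate_names)
            if covariate_names is not None
            else [f"x{i}" for i in range(self.covariates.shape[1])]
        )
        self.target_name = target_name
        self.nobs = self.target.size

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame, lesion_load,
                       target: str = SCORE_COLUMNS[0],
                       covariate_columns=COVARIATE_COLUMNS) -> "LesionDeficitModel":
        """Build from a cohort table plus a per-patient lesion-load vector."""
        cov = list(covariate_columns)
        model = cls(
            target=cohort[target].to_numpy(dtype=float),
            lesion_load=lesion_load,
            covariates=cohort.loc[:, cov].to_numpy(dtype=float),
            covariate_names=cov,
            target_name=target,
        )
        model._cohort = cohort.reset_index(drop=True)
        return model

    def fit(self) -> "LesionDeficitResults":
        """Estimate the partial correlation and return a results object."""
        pc = partial_correlation(self.target, self.lesion_load, self.covariates)
        return LesionDeficitResults(self, pc)


class LesionDeficitResults:
    """Fitted ROI lesion-deficit effect with interval and resampling tools."""

    def __init__(self, model: LesionDeficitModel, pc: PartialCorrResult):
        self.model = model
        self._pc = pc

    # -- plain accessors -------------------------------------------------
    @property
    def r_partial(self) -> float:
        return self._pc.r_partial

    @property
    def r2(self) -> float:
        return self._pc.r2

    @property
    def t_stat(self) -> float:
        return self._pc.t_stat

    @property
    def df(self) -> int:
        return self._pc.df

    @property
    def p_value(self) -> float:
        return self._pc.p_two_sided

    @property
    def nobs(self) -> int:
        return self._pc.n

    @property
    def k_covariates(self) -> int:
        return self._pc.k

    def credible_interval(self, level: float = 0.95) -> CredibleInterval:
        """Flat-prior credible interval for R² on the Fisher-z scale."""
        sign = -1 if self.r_partial < 0 else 1
        return credible_interval_r2(self.r2, self.nobs, self.k_covariates,
                                    level=level, sign=sign)

    def power_at(self, n: int, alpha: float = 0.05) -> float:
        """Analytic power to detect the fitted R² at sample size n."""
        return analytic_power(self.r2, n, self.k_covariates, alpha)

    def sign_error_at(self, n: int) -> float:
        """Probability a size-n sample inverts the effect direction."""
        return sign_error_probability(self.r2, n, self.k_covariates)

    def summary(self, level: float = 0.95) -> SimpleTable:
        ci = self.credible_interval(level)
        rows = [
            ("n patients", f"{self.nobs}"),
            ("covariates (k)", f"{self.k_covariates}"),
            ("partial r", f"{self.r_partial:.4f}"),
            ("R2 (variance explained)", f"{self.r2:.4f}"),
            ("t statistic", f"{self.t_stat:.3f}"),
            ("degrees of freedom", f"{self.df}"),
            ("p (two-sided)", f"{self.p_value:.3g}"),
            (f"{level:.0%} credible interval (R2)",
             f"[{ci.lower_r2:.2f}, {ci.upper_r2:.2f}]"),
        ]
        return SimpleTable(
            [[v] for _, v in rows],
            headers=["value"],
            stubs=[s for s, _ in rows],
            title=f"ROI lesion-deficit effect on {self.model.target_name}",
        )

    # -- resampling ------------------------------------------------------
    def bootstrap_study(
        self,
        sizes=_boot.DEFAULT_SIZES,
        B: int = 6000,
        with_replacement: bool = True,
        seed: int | None = None,
        alphas=(0.05, 0.001),
    ) -> "BootstrapStudyResults":
        """Resample the fitted cohort and study effect-size reproducibility."""
        cohort = getattr(self.model, "_cohort", None)
        if cohort is None:
            cohort = pd.DataFrame(
                {self.model.target_name: self.model.target,
                 **{name: self.model.covariates[:, j]
                    for j, name in enumerate(self.model.covariate_names)}})
        records = _boot.run_resampling_study(
            cohort.assign(**{self.model.target_name: self.model.target}),
            self.model.lesion_load,
            sizes=sizes, B=B, with_replacement=with_replacement, seed=seed,
        )
        return BootstrapStudyResults(self, records, alphas=alphas)


class BootstrapStudyResults:
    """Resample records plus the table summaries of the reproducibility study."""

    def __init__(self, results: LesionDeficitResults, records: pd.DataFrame,
                 alphas=(0.05, 0.001)):
        self.results = results
        self.records = records
        self.alphas = tuple(alphas)

    @property
    def sizes(self):
        return tuple(sorted(self.records["size"].unique()))

    def proportion_significant(self, alpha: float = 0.05) -> pd.Series:
        """Fraction of resamples with p < alpha, per size."""
        return self.records.groupby("size").apply(
            lambda g: float((g["p"] < alpha).mean()), include_groups=False)

    def summarize_by_significance(self, alphas=None) -> pd.DataFrame:
        return _boot.summarize_by_significance(
            self.records, alphas or self.alphas)

    def classify_against_interval(self, interval=None, alpha=0.05) -> pd.DataFrame:
        if interval is None:
            interval = self.results.credible_interval()
        return _boot.classify_against_interval(self.records, interval, alpha)

    def select_deciles(self) -> pd.DataFrame:
        return _boot.select_decile_resamples(self.records)

    def wrong_sign_fraction(self) -> pd.Series:
        """Fraction of resamples whose effect has the wrong direction."""
        full_sign = 1 if self.results.r_partial >= 0 else -1
        return self.records.groupby("size").apply(
            lambda g: float((g["sign"] != full_sign).mean()), include_groups=False)

    # -- plotting --------------------------------------------------------
    def plot_effect_distributions(self, ax=None):
        """Box plots of the R² distribution per sample size."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        data = [self.records.loc[self.records["size"] == s, "r2"] for s in self.sizes]
        ax.boxplot(data, tick_labels=[str(s) for s in self.sizes], showfliers=False)
        ax.axhline(self.results.r2, color="crimson", ls="--", lw=1,
                   label=f"full-sample R2 = {self.results.r2:.2f}")
        ax.set_xlabel("sample size")
        ax.set_ylabel("R2 (partial)")
        ax.set_title("Effect-size distributions across bootstrap resamples")
        ax.legend()
        return ax

    def plot_significance_histogram(self, size=None, alpha=0.05, ax=None):
        """Histogram of R² at one size, split by significance."""
        import matplotlib.pyplot as plt

        if size is None:
            size = min(self.sizes)
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        grp = self.records[self.records["size"] == size]
        sig = grp["p"] < alpha
        bins = np.linspace(0, max(grp["r2"].max(), 0.2), 40)
        ax.hist(grp.loc[~sig, "r2"], bins=bins, alpha=0.6,
                label=f"p >= {alpha}", color="steelblue")
        ax.hist(grp.loc[sig, "r2"], bins=bins, alpha=0.6,
                label=f"p < {alpha}", color="darkorange")
        ax.axvline(self.results.r2, color="crimson", ls="--", lw=1)
        ax.set_xlabel("R2 (partial)")
        ax.set_ylabel("resamples")
        ax.set_title(f"N = {size}: winner's curse in significant resamples")
        ax.legend()
        return ax
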