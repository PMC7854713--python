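"""Estimation of initial concentrations and decay constants from
censored concentration series, with group contrasts.

Model structure
---------------
Decay is first-order: within each tank x target series the response
is ``log_e(C_t / C_0)`` and its slope over the initial log-linear
window (default 0-72 h) is ``-k``.  Two fitting routes share one
result surface:

* ``"mixed"`` — a linear mixed-effects model (statsmodels ``MixedLM``)
  of the log concentration ratio on time with per-target slopes, a
  quantitative abundance covariate (centered, entering the slope), and
  a random intercept per tank;
* ``"two_stage"`` — per-series ordinary least squares slopes pooled
  per target with time-leverage (Sxx) weights and a residual variance
  pooled across tanks.  This equals the fixed-tank-intercept pooled
  OLS estimator and gives exact small-sample Wald inference when the
  lognormal noise model holds.

``"auto"`` tries the mixed model and falls back to the two-stage
estimator when the mixed fit does not converge (small or degenerate
designs), logging the downgrade.  Non-detects are dropped from fits
(the default censoring policy); near the detection limit this biases
k upward, which is documented rather than silently corrected.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import (
    ConcentrationSeries,
    GeneTarget,
    NotEstimableError,
    ValidationError,
)
from .kinetics import DecayFit

log = logging.getLogger("ednaclock")


@dataclass(frozen=True)
class ModelSpec:
    """Analysis window and censoring policy for decay fitting."""

    window_h: Tuple[float, float] = (0.0, 72.0)
    censor_policy: str = "drop"  # "drop" | "refuse"

    def __post_init__(self) -> None:
        if not self.window_h[0] < self.window_h[1]:
            raise ValidationError("window start must precede window end")
        if self.censor_policy not in ("drop", "refuse"):
            raise ValidationError("censor_policy must be 'drop' or 'refuse'")


def normalize_series(
    series: ConcentrationSeries,
) -> List[Tuple[float, Optional[float]]]:
    """Normalize a series to C' = C_t / C_0.

    Returns (time_h, C') pairs; censored points keep ``None``.  The
    value at t = 0 is exactly 1.

    Raises
    ------
    NotEstimableError
        No detection at t = 0 with positive concentration; the series
        cannot anchor a decay fit.
    """
    m0 = series.at_time(0.0)
    if m0 is None or m0.censored or not m0.copies_per_ml or m0.copies_per_ml <= 0:
        raise NotEstimableError(
            f"series {series.tank_id}/{series.target.label}: no positive "
            "detection at t = 0; cannot normalize"
        )
    c0 = m0.copies_per_ml
    return [
        (m.time_h, None if m.censored else m.copies_per_ml / c0)
        for m in series.measurements
    ]


# ---------------------------------------------------------------------------
# model frames


def _decay_frame(
    series_list: Sequence[ConcentrationSeries], spec: ModelSpec
) -> Tuple[pd.DataFrame, Dict[str, int], Dict[tuple, str]]:
    """Long frame of log_e(C_t/C_0) rows inside the window.

    Returns (frame, bookkeeping counts, skip reasons per series).
    """
    lo, hi = spec.window_h
    rows = []
    counts = {"censored_dropped": 0, "series_skipped": 0, "outside_window": 0}
    skipped: Dict[tuple, str] = {}
    for s in series_list:
        in_window = [m for m in s.measurements if lo <= m.time_h <= hi]
        n_cens = sum(m.censored for m in in_window)
        if spec.censor_policy == "refuse" and n_cens:
            raise ValidationError(
                f"censor_policy='refuse': series {s.tank_id}/{s.target.label} "
                f"has {n_cens} censored point(s) inside the window"
            )
        counts["censored_dropped"] += n_cens
        counts["outside_window"] += len(s) - len(in_window)
        try:
            norm = dict(normalize_series(s))
        except NotEstimableError as exc:
            counts["series_skipped"] += 1
            skipped[(s.tank_id, s.target.key, s.sample)] = str(exc)
            continue
        usable = [
            (m.time_h, norm[m.time_h])
            for m in in_window
            if not m.censored and norm[m.time_h] and norm[m.time_h] > 0
        ]
        if len(usable) < 2:
            counts["series_skipped"] += 1
            skipped[(s.tank_id, s.target.key, s.sample)] = "fewer than 2 usable detections in window"
            continue
        for t, cprime in usable:
            rows.append(
                {
                    "tank_id": s.tank_id,
                    "sample": s.sample,
                    "series": f"{s.tank_id}/{s.sample}",
                    "tkey": s.target.label,
                    "abundance": float(s.abundance if s.abundance is not None else 0),
                    "time_h": t,
                    "log_cprime": math.log(cprime),
                }
            )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["abund_c"] = frame["abundance"] - frame["abundance"].mean()
    return frame, counts, skipped


def _t0_frame(series_list: Sequence[ConcentrationSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        m0 = s.at_time(0.0)
        if m0 is None or m0.censored or not m0.copies_per_ml:
            continue
        rows.append(
            {
                "tank_id": s.tank_id,
                "sample": s.sample,
                "tkey": s.target.label,
                "abundance": float(s.abundance if s.abundance is not None else 0),
                "log_c0": math.log(m0.copies_per_ml),
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["abund_c"] = frame["abundance"] - frame["abundance"].mean()
    return frame


def _targets_by_label(series_list: Sequence[ConcentrationSeries]) -> Dict[str, GeneTarget]:
    return {s.target.label: s.target for s in series_list}


# ---------------------------------------------------------------------------
# contrasts


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise group difference on the estimation scale."""

    pair: Tuple[str, str]
    estimate: float
    se: float
    p_value: float
    adjusted_p: float
    adjustment: str = "holm"

    def reversed(self) -> "ContrastResult":
        return ContrastResult(
            pair=(self.pair[1], self.pair[0]),
            estimate=-self.estimate,
            se=self.se,
            p_value=self.p_value,
            adjusted_p=self.adjusted_p,
            adjustment=self.adjustment,
        )


def _z_p(est: float, se: float) -> float:
    if se > 0:
        return float(2.0 * stats.norm.sf(abs(est) / se))
    return 1.0 if est == 0 else 0.0


def pairwise_contrasts(
    estimates: Mapping,
    by: Optional[str] = None,
    adjustment: str = "holm",
) -> List[ContrastResult]:
    """All pairwise group differences with multiplicity-adjusted p-values.

    Parameters
    ----------
    estimates : mapping
        ``{key: (estimate, se)}``.  When keys are :class:`GeneTarget`,
        ``by`` groups them by attribute — ``"genome"``,
        ``"nucleic_acid"``, ``"rna_class"`` (group mean of member
        targets), or ``"fragment_length"`` (short-vs-long pairs within
        the same gene and nucleic acid).  Any other keys (e.g.
        abundance levels) each form their own group.
    adjustment : str
        Family-wise adjustment method, Holm by default.

    Group estimates are means of independent member estimates with
    ``se = sqrt(sum se_i^2) / m``; differences are tested with
    two-sided z-tests (exact ties give p = 1).
    """
    keys = list(estimates.keys())
    if not keys:
        return []
    gene_keys = all(isinstance(k, GeneTarget) for k in keys)

    pairs: List[Tuple[str, str, float, float]] = []  # (labelA, labelB, est, se)
    if gene_keys and by == "fragment_length":
        bygene: Dict[tuple, list] = {}
        for t in keys:
            bygene.setdefault((t.gene, t.nucleic_acid.value), []).append(t)
        for members in bygene.values():
            members = sorted(members, key=lambda t: t.amplicon_length)
            for a, b in itertools.combinations(members, 2):  # short minus long
                ea, sa = estimates[a]
                eb, sb = estimates[b]
                pairs.append((a.label, b.label, ea - eb, math.hypot(sa, sb)))
    else:
        if gene_keys and by in ("genome", "nucleic_acid", "rna_class"):
            attr = {"genome": "genome", "nucleic_acid": "nucleic_acid", "rna_class": "rna_class"}[by]
            groups: Dict[str, list] = {}
            for t in keys:
                groups.setdefault(getattr(t, attr).value, []).append(estimates[t])
        else:
            groups = {str(k): [estimates[k]] for k in keys}
        if len(groups) < 2:
            log.warning("pairwise_contrasts: a single group, nothing to compare")
            return []
        summary = {}
        for label, members in groups.items():
            ests = [e for e, _ in members]
            ses = [s for _, s in members]
            m = len(members)
            summary[label] = (
                float(np.mean(ests)),
                math.sqrt(sum(s * s for s in ses)) / m,
            )
        for a, b in itertools.combinations(sorted(summary), 2):
            ea, sa = summary[a]
            eb, sb = summary[b]
            pairs.append((a, b, ea - eb, math.hypot(sa, sb)))

    if not pairs:
        log.warning("pairwise_contrasts: no comparable pairs")
        return []
    raw_p = [_z_p(est, se) for _, _, est, se in pairs]
    if len(raw_p) > 1:
        adj = multipletests(raw_p, method=adjustment)[1]
    else:
        adj = raw_p
    return [
        ContrastResult(
            pair=(a, b),
            estimate=est,
            se=se,
            p_value=p,
            adjusted_p=float(ap),
            adjustment=adjustment,
        )
        for (a, b, est, se), p, ap in zip(pairs, raw_p, adj)
    ]


# ---------------------------------------------------------------------------
# two-stage estimators


def _series_slopes(frame: pd.DataFrame) -> pd.DataFrame:
    """Per (target, series) OLS slope of log C' on time, with leverage
    Sxx, residual sum of squares and point count."""
    recs = []
    for (tkey, series_id), g in frame.groupby(["tkey", "series"], sort=True):
        t = g["time_h"].to_numpy()
        y = g["log_cprime"].to_numpy()
        n = len(t)
        tbar = t.mean()
        sxx = float(((t - tbar) ** 2).sum())
        if n < 2 or sxx <= 0:
            continue
        b = float(((t - tbar) * (y - y.mean())).sum() / sxx)
        a = float(y.mean() - b * tbar)
        rss = float(((y - a - b * t) ** 2).sum())
        recs.append(
            {
                "tkey": tkey,
                "series": series_id,
                "abundance": float(g["abundance"].iloc[0]),
                "slope": b,
                "sxx": sxx,
                "rss": rss,
                "n": n,
            }
        )
    return pd.DataFrame(recs)


def _pool_slopes(sl: pd.DataFrame) -> Tuple[float, float, int]:
    """Leverage-weighted pooled slope with pooled-residual Wald SE.

    Equivalent to pooled OLS with a fixed intercept per series; when
    each series contributes only 2 points (zero residual df) the SE
    falls back to the between-series scatter of slopes.
    """
    w = sl["sxx"].to_numpy()
    b = sl["slope"].to_numpy()
    slope = float((w * b).sum() / w.sum())
    df = int((sl["n"] - 2).sum())
    if df > 0:
        sigma2 = float(sl["rss"].sum()) / df
        se = math.sqrt(sigma2 / w.sum())
    elif len(b) > 1:
        se = float(np.std(b, ddof=1) / math.sqrt(len(b)))
    else:
        se = 0.0
    n_obs = int(sl["n"].sum())
    return slope, se, n_obs


# ---------------------------------------------------------------------------
# mixed-model machinery


def _mixedlm_fit(formula: str, frame: pd.DataFrame):
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm(formula, frame, groups=frame["tank_id"])
        # gradient optimizers occasionally collapse into the degenerate
        # zero-residual-variance optimum (llf = inf); Powell is robust here
        res = md.fit(reml=True, method="powell", maxiter=2000)
        if (
            not res.converged
            or not np.isfinite(res.llf)
            or not np.all(np.isfinite(res.fe_params))
        ):
            raise RuntimeError("mixed model did not converge")
        if not np.all(np.isfinite(np.diag(res.cov_params())[: len(res.fe_params)])):
            raise RuntimeError("mixed model covariance is degenerate")
    return res


def _linear_combo(res, weights: Dict[str, float]) -> Tuple[float, float]:
    """Estimate and SE of sum_i w_i * beta_i for named fixed effects."""
    names = list(res.fe_params.index)
    L = np.zeros(len(names))
    for name, w in weights.items():
        if name not in names:
            raise KeyError(name)
        L[names.index(name)] = w
    cov = np.asarray(res.cov_params())[: len(names), : len(names)]
    est = float(L @ res.fe_params.to_numpy())
    var = float(L @ cov @ L)
    return est, math.sqrt(max(var, 0.0))


# ---------------------------------------------------------------------------
# models and results


@dataclass
class DecayResults:
    """Per-target decay fits plus the abundance effect on k.

    ``fits`` maps :class:`GeneTarget` to :class:`DecayFit`;
    ``not_estimable`` carries a reason per target that could not be
    fitted.  ``abundance_effect`` is (dk/d organism, se) in 1/h per
    organism, or None when abundance does not vary.
    """

    fits: Dict[GeneTarget, DecayFit]
    not_estimable: Dict[GeneTarget, str]
    abundance_effect: Optional[Tuple[float, float]]
    method: str
    spec: ModelSpec
    counts: Dict[str, int] = field(default_factory=dict)

    def contrasts(
        self,
        by: str,
        targets: Optional[Sequence[GeneTarget]] = None,
        adjustment: str = "holm",
    ) -> List[ContrastResult]:
        """Pairwise contrasts of decay constants between groups of targets."""
        pool = {
            t: (f.k_hat, f.se_k)
            for t, f in self.fits.items()
            if targets is None or t in set(targets)
        }
        return pairwise_contrasts(pool, by=by, adjustment=adjustment)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, f in self.fits.items():
            try:
                hl_ci = f.half_life_ci_h
            except Exception:
                hl_ci = (math.nan, math.nan)
            rows.append(
                {
                    "target": t.label,
                    "k_per_h": f.k_hat,
                    "se_k": f.se_k,
                    "half_life_h": f.half_life_h if f.k_hat > 0 else math.nan,
                    "half_life_lo_h": hl_ci[0],
                    "half_life_hi_h": hl_ci[1],
                    "n_obs": f.n_obs,
                }
            )
        for t, reason in self.not_estimable.items():
            rows.append({"target": t.label, "k_per_h": math.nan, "note": reason})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "First-order decay fits "
            f"(window {self.spec.window_h[0]:g}-{self.spec.window_h[1]:g} h, "
            f"method={self.method}, censored dropped={self.counts.get('censored_dropped', 0)})",
            self.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        if self.abundance_effect is not None:
            est, se = self.abundance_effect
            lines.append(
                f"abundance effect on k: {est:+.3e} 1/h per organism (se {se:.1e})"
            )
        return "\n".join(lines)


class DecayModel:
    """First-order decay model over a set of concentration series.

    Statsmodels-style: construct from data, then :meth:`fit` returns a
    :class:`DecayResults`.
    """

    def __init__(
        self,
        series: Sequence[ConcentrationSeries],
        spec: Optional[ModelSpec] = None,
        window_h: Optional[Tuple[float, float]] = None,
        censor_policy: Optional[str] = None,
    ):
        if spec is None:
            spec = ModelSpec(
                window_h=window_h or (0.0, 72.0),
                censor_policy=censor_policy or "drop",
            )
        elif window_h is not None or censor_policy is not None:
            raise ValidationError("pass either spec or window/censor overrides")
        self.series = list(series)
        self.spec = spec
        self.targets = _targets_by_label(self.series)
        self.frame, self.counts, self.skipped = _decay_frame(self.series, spec)

    def fit(self, method: str = "auto") -> DecayResults:
        if method not in ("auto", "mixed", "two_stage"):
            raise ValidationError("method must be auto, mixed or two_stage")
        if self.frame.empty:
            return DecayResults(
                fits={},
                not_estimable={
                    t: "no usable series" for t in self.targets.values()
                },
                abundance_effect=None,
                method="none",
                spec=self.spec,
                counts=self.counts,
            )
        if method in ("auto", "mixed"):
            try:
                return self._fit_mixed()
            except Exception as exc:
                if method == "mixed":
                    raise
                log.info("mixed decay fit unavailable (%s); two-stage fallback", exc)
        return self._fit_two_stage()

    # -- two-stage ---------------------------------------------------------

    def _fit_two_stage(self) -> DecayResults:
        sl = _series_slopes(self.frame)
        fits: Dict[GeneTarget, DecayFit] = {}
        not_est: Dict[GeneTarget, str] = {}
        for label, target in self.targets.items():
            g = sl[sl["tkey"] == label]
            if g.empty:
                not_est[target] = self.skipped.get(
                    next(
                        (k for k in self.skipped if k[1] == target.key),
                        ("", target.key, ""),
                    ),
                    "no usable series",
                )
                continue
            slope, se, n_obs = _pool_slopes(g)
            fits[target] = DecayFit(
                k_hat=max(0.0, -slope),
                se_k=se,
                n_obs=n_obs,
                window_h=self.spec.window_h,
                target_label=target.label,
            )
        abund = self._abundance_effect_two_stage(sl)
        return DecayResults(
            fits=fits,
            not_estimable=not_est,
            abundance_effect=abund,
            method="two_stage",
            spec=self.spec,
            counts=self.counts,
        )

    def _abundance_effect_two_stage(
        self, sl: pd.DataFrame
    ) -> Optional[Tuple[float, float]]:
        if sl.empty or sl["abundance"].nunique() < 2:
            return None
        import statsmodels.api as sm

        X = pd.get_dummies(sl["tkey"], drop_first=False, dtype=float)
        X["abundance"] = sl["abundance"]
        res = sm.WLS(sl["slope"], X, weights=sl["sxx"]).fit()
        return (-float(res.params["abundance"]), float(res.bse["abundance"]))

    # -- mixed -------------------------------------------------------------

    def _fit_mixed(self) -> DecayResults:
        frame = self.frame
        multi_abund = frame["abundance"].nunique() > 1
        multi_target = frame["tkey"].nunique() > 1
        terms = ["time_h"]
        if multi_target:
            terms += ["C(tkey)", "time_h:C(tkey)"]
        if multi_abund:
            terms += ["abund_c", "time_h:abund_c"]
            if multi_target:
                terms += ["C(tkey):abund_c"]
        formula = "log_cprime ~ " + " + ".join(terms)
        res = _mixedlm_fit(formula, frame)
        labels = sorted(frame["tkey"].unique())
        base = labels[0]
        fits: Dict[GeneTarget, DecayFit] = {}
        for label in labels:
            weights = {"time_h": 1.0}
            if multi_target and label != base:
                weights[f"time_h:C(tkey)[T.{label}]"] = 1.0
            est, se = _linear_combo(res, weights)
            n_obs = int((frame["tkey"] == label).sum())
            fits[self.targets[label]] = DecayFit(
                k_hat=max(0.0, -est),
                se_k=se,
                n_obs=n_obs,
                window_h=self.spec.window_h,
                target_label=label,
            )
        abund = None
        if multi_abund:
            est, se = _linear_combo(res, {"time_h:abund_c": 1.0})
            abund = (-est, se)
        not_est = {
            self.targets[label]: "no usable series"
            for label in self.targets
            if label not in labels
        }
        return DecayResults(
            fits=fits,
            not_estimable=not_est,
            abundance_effect=abund,
            method="mixed",
            spec=self.spec,
            counts=self.counts,
        )


@dataclass
class InitialConcentrationResults:
    """Per-target marginal mean log_e initial concentration and the
    abundance effect on shedding."""

    means: Dict[GeneTarget, Tuple[float, float]]  # (log_e copies/mL, se)
    not_estimable: Dict[GeneTarget, str]
    abundance_effect: Optional[Tuple[float, float]]  # d log_e C0 / d organism
    method: str

    def contrasts(
        self,
        by: str,
        targets: Optional[Sequence[GeneTarget]] = None,
        adjustment: str = "holm",
    ) -> List[ContrastResult]:
        pool = {
            t: v
            for t, v in self.means.items()
            if targets is None or t in set(targets)
        }
        return pairwise_contrasts(pool, by=by, adjustment=adjustment)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"target": t.label, "log_c0": m, "se": s}
            for t, (m, s) in self.means.items()
        ]
        rows += [
            {"target": t.label, "log_c0": math.nan, "note": r}
            for t, r in self.not_estimable.items()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Initial log_e concentrations (method={self.method})",
            self.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        if self.abundance_effect is not None:
            est, se = self.abundance_effect
            lines.append(
                f"abundance effect on log_e C0: {est:+.4f} per organism (se {se:.4f})"
            )
        return "\n".join(lines)


class InitialConcentrationModel:
    """Model of log_e concentration at t = 0 on target identity and
    abundance, with a random tank intercept."""

    def __init__(self, series: Sequence[ConcentrationSeries]):
        self.series = list(series)
        self.targets = _targets_by_label(self.series)
        self.frame = _t0_frame(self.series)

    def fit(self, method: str = "auto") -> InitialConcentrationResults:
        if method not in ("auto", "mixed", "ols"):
            raise ValidationError("method must be auto, mixed or ols")
        frame = self.frame
        if frame.empty:
            return InitialConcentrationResults(
                means={},
                not_estimable={t: "no t=0 detections" for t in self.targets.values()},
                abundance_effect=None,
                method="none",
            )
        if len({s.tank_id for s in self.series}) < 2:
            raise NotEstimableError("initial-concentration model needs >= 2 tanks")
        if method in ("auto", "mixed"):
            try:
                return self._fit(frame, mixed=True)
            except Exception as exc:
                if method == "mixed":
                    raise
                log.info("mixed t0 fit unavailable (%s); OLS fallback", exc)
        return self._fit(frame, mixed=False)

    def _fit(self, frame: pd.DataFrame, mixed: bool) -> InitialConcentrationResults:
        import statsmodels.formula.api as smf

        multi_abund = frame["abundance"].nunique() > 1
        formula = "log_c0 ~ 0 + C(tkey)"
        if multi_abund:
            formula += " + C(tkey):abund_c"
        if mixed:
            res = _mixedlm_fit(formula, frame)
            names = list(res.fe_params.index)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.ols(formula, frame).fit()
            names = list(res.params.index)

        def combo(weights):
            if mixed:
                return _linear_combo(res, weights)
            L = np.zeros(len(names))
            for name, w in weights.items():
                L[names.index(name)] = w
            est = float(L @ res.params.to_numpy())
            var = float(L @ np.asarray(res.cov_params()) @ L)
            return est, math.sqrt(max(var, 0.0))

        labels = sorted(frame["tkey"].unique())
        means: Dict[GeneTarget, Tuple[float, float]] = {}
        for label in labels:
            means[self.targets[label]] = combo({f"C(tkey)[{label}]": 1.0})
        abund = None
        if multi_abund:
            w = {f"C(tkey)[{label}]:abund_c": 1.0 / len(labels) for label in labels}
            abund = combo(w)
        not_est = {
            self.targets[label]: "no t=0 detections"
            for label in self.targets
            if label not in labels
        }
        return InitialConcentrationResults(
            means=means,
            not_estimable=not_est,
            abundance_effect=abund,
            method="mixed" if mixed else "ols",
        )


# ---------------------------------------------------------------------------
# functional wrappers (the module-level operation surface)


def fit_decay(
    series: Sequence[ConcentrationSeries],
    spec: Optional[ModelSpec] = None,
    method: str = "auto",
) -> DecayResults:
    """Fit per-target decay constants; see :class:`DecayModel`."""
    return DecayModel(series, spec=spec).fit(method=method)


def fit_initial_concentration(
    series: Sequence[ConcentrationSeries], method: str = "auto"
) -> InitialConcentrationResults:
    """Fit per-target initial concentrations; see
    :class:`InitialConcentrationModel`."""
    return InitialConcentrationModel(series).fit(method=method)
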