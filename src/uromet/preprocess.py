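"""Curation and normalization of untargeted LC-MS feature tables.

Stages, in the order they are applied by :func:`run_preprocessing`:

1. blank filter — drop features whose blank signal approaches QC-pool signal;
2. dilution-linearity filter — drop features whose response across the QC
   dilution series has Pearson r below a threshold (default 0.6);
3. presence filter — keep features observed in strictly more than a fraction
   (default 2/3) of study injections;
4. per-batch LOESS drift correction on QC pools (span 0.75);
5. probabilistic quotient normalization (PQN) against a median reference
   spectrum, correcting urine dilution;
6. low-value imputation of left-censored missing entries;
7. replicate aggregation (mean of 2, median of 3-4);
8. chromatographic-mode merge by feature-id concatenation.

Tables are oriented features x injections (the on-disk TSV convention).
The transformer classes operate on the scikit-learn orientation,
injections (samples) x features, and accept the injection metadata as a
``meta`` fit parameter aligned with the rows of ``X``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "LoessConfig",
    "PqnResult",
    "BlankFeatureFilter",
    "DilutionLinearityFilter",
    "PresenceFilter",
    "LoessDriftCorrector",
    "PQNNormalizer",
    "LowValueImputer",
    "ReplicateAggregator",
    "filter_blank_features",
    "filter_dilution_linearity",
    "filter_presence",
    "loess_drift_correct",
    "pqn_normalize",
    "impute_missing",
    "aggregate_replicates",
    "run_preprocessing",
]


@dataclass
class FilterConfig:
    """Thresholds of the three feature-curation filters."""

    dilution_r_min: float = 0.6
    presence_fraction: float = 2.0 / 3.0
    blank_ratio_max: float = 0.5

    def validate(self) -> None:
        for name in ("dilution_r_min", "presence_fraction", "blank_ratio_max"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


@dataclass
class LoessConfig:
    span: float = 0.75
    min_qc_per_batch: int = 5
    per_batch: bool = True

    def validate(self) -> None:
        if not 0.0 < self.span <= 1.0:
            raise ValueError(f"span must lie in (0, 1], got {self.span}")
        if self.min_qc_per_batch < 3:
            raise ValueError("min_qc_per_batch must be >= 3")


@dataclass
class PqnResult:
    normalized: pd.DataFrame  # features x injections
    factors: pd.Series  # per injection, > 0
    reference: pd.Series  # per feature


def _check_meta(X: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    if meta is None:
        raise ValueError("injection metadata ('meta') is required")
    meta = meta.set_index("injection_id") if "injection_id" in meta.columns else meta
    missing = [i for i in X.index if i not in meta.index]
    if missing:
        raise ValueError(f"injections absent from metadata: {missing[:5]}")
    return meta.loc[X.index]


class _FeatureDropper(BaseEstimator, TransformerMixin):
    """Base for filters that learn a set of features to drop."""

    removed_ids_: list[str]

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        keep = [f for f in X.columns if f not in set(self.removed_ids_)]
        return X[keep]


class BlankFeatureFilter(_FeatureDropper):
    """Remove features detected in blanks at levels comparable to QC pools.

    A feature is removed when mean(blank) / mean(QC pool) >= ``blank_ratio_max``
    (missing treated as zero signal). A feature with zero QC signal is removed
    if it has any blank signal.
    """

    def __init__(self, blank_ratio_max: float = 0.5):
        self.blank_ratio_max = blank_ratio_max

    def fit(self, X: pd.DataFrame, y=None, *, meta: pd.DataFrame):
        meta = _check_meta(X, meta)
        blanks = X.loc[(meta["type"] == "blank").to_numpy()]
        qcs = X.loc[(meta["type"] == "qc_pool").to_numpy()]
        if blanks.empty or qcs.empty:
            raise ValueError(
                "blank filtering needs at least one blank and one qc_pool injection; "
                "omit this stage explicitly if the design has no blanks"
            )
        blank_mean = blanks.fillna(0.0).mean(axis=0)
        qc_mean = qcs.fillna(0.0).mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = blank_mean / qc_mean
        ratio = ratio.where(qc_mean > 0, np.where(blank_mean > 0, np.inf, 0.0))
        self.removed_ids_ = list(X.columns[(ratio >= self.blank_ratio_max).to_numpy()])
        return self


class DilutionLinearityFilter(_FeatureDropper):
    """Remove features whose QC dilution-series response is not linear.

    Pearson r between abundance and dilution level across the series; missing
    values in the series count as zero abundance; undefined r (zero variance)
    is treated as failing.
    """

    def __init__(self, dilution_r_min: float = 0.6):
        self.dilution_r_min = dilution_r_min

    def fit(self, X: pd.DataFrame, y=None, *, meta: pd.DataFrame):
        meta = _check_meta(X, meta)
        series = meta["type"] == "qc_dilution"
        levels = meta.loc[series, "dilution_level"].astype(float)
        if levels.nunique() < 3:
            raise ValueError("dilution-linearity filtering needs >= 3 dilution levels")
        sub = X.loc[series.to_numpy()].fillna(0.0).to_numpy()
        lv = levels.to_numpy()
        lv_c = lv - lv.mean()
        sub_c = sub - sub.mean(axis=0)
        denom = np.sqrt((lv_c**2).sum() * (sub_c**2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (lv_c @ sub_c) / denom
        r = np.where(np.isfinite(r), r, 0.0)
        self.r_ = pd.Series(r, index=X.columns)
        self.removed_ids_ = list(X.columns[r < self.dilution_r_min])
        return self


class PresenceFilter(_FeatureDropper):
    """Keep features non-missing in strictly more than ``presence_fraction``
    of study injections."""

    def __init__(self, presence_fraction: float = 2.0 / 3.0):
        self.presence_fraction = presence_fraction

    def fit(self, X: pd.DataFrame, y=None, *, meta: pd.DataFrame):
        meta = _check_meta(X, meta)
        study = X.loc[(meta["type"] == "study").to_numpy()]
        if study.empty:
            raise ValueError("no study injections found")
        frac = study.notna().sum(axis=0) / len(study)
        self.presence_ = frac
        self.removed_ids_ = list(X.columns[(frac <= self.presence_fraction).to_numpy()])
        return self


class LoessDriftCorrector(BaseEstimator, TransformerMixin):
    """Per-batch LOESS correction of injection-order signal drift.

    For each feature and batch, a degree-1 LOESS (span default 0.75, no
    robustness iterations) is fit to QC-pool abundance vs injection order.
    The correction factor at any order is the fitted value (interpolated
    between QC orders, held flat beyond the first/last QC) divided by the
    median fitted value at the QC orders; every injection in the batch is
    divided by its factor. Non-positive fitted values are clamped to the
    smallest positive fitted value. Batches with fewer than
    ``min_qc_per_batch`` QC pools are left uncorrected (logged warning).
    """

    def __init__(self, span: float = 0.75, min_qc_per_batch: int = 5, per_batch: bool = True):
        self.span = span
        self.min_qc_per_batch = min_qc_per_batch
        self.per_batch = per_batch

    def fit(self, X: pd.DataFrame, y=None, *, meta: pd.DataFrame):
        meta = _check_meta(X, meta)
        factors = pd.DataFrame(1.0, index=X.index, columns=X.columns)
        batches = meta["batch"].unique() if self.per_batch else ["__all__"]
        for b in batches:
            in_batch = np.ones(len(meta), bool) if b == "__all__" else (meta["batch"] == b).to_numpy()
            is_qc = in_batch & (meta["type"] == "qc_pool").to_numpy()
            if is_qc.sum() < self.min_qc_per_batch:
                logger.warning(
                    "batch %r has %d QC pools (< %d); drift correction skipped",
                    b, int(is_qc.sum()), self.min_qc_per_batch,
                )
                continue
            order = meta.loc[in_batch, "injection_order"].to_numpy(float)
            qc_order = meta.loc[is_qc, "injection_order"].to_numpy(float)
            qc_vals = X.loc[is_qc]
            for feat in X.columns:
                yv = qc_vals[feat].to_numpy(float)
                ok = np.isfinite(yv)
                if ok.sum() < 3:
                    continue
                fitted = lowess(yv[ok], qc_order[ok], frac=self.span, it=0, return_sorted=True)
                fx, fy = fitted[:, 0], fitted[:, 1]
                if (fy <= 0).any():
                    pos = fy[fy > 0]
                    if pos.size == 0:
                        continue
                    fy = np.where(fy <= 0, pos.min(), fy)
                med = np.median(fy)
                if med <= 0:
                    continue
                # flat extrapolation beyond terminal QCs is np.interp's default
                f_all = np.interp(order, fx, fy) / med
                factors.loc[in_batch, feat] = f_all
        self.factors_ = factors
        self._fit_index = X.index
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not X.index.equals(self._fit_index):
            raise ValueError("LoessDriftCorrector corrects the injections it was fit on")
        return X / self.factors_


class PQNNormalizer(BaseEstimator, TransformerMixin):
    """Probabilistic quotient normalization.

    The reference spectrum is the per-feature median over the reference scope
    (QC pools by default, or all study injections). Each injection is divided
    by the median of its feature-wise quotients against the reference,
    computed over features non-missing in both and positive in the reference.
    """

    def __init__(self, reference_scope: str = "qc", min_shared_features: int = 10):
        self.reference_scope = reference_scope
        self.min_shared_features = min_shared_features

    def fit(self, X: pd.DataFrame, y=None, *, meta: pd.DataFrame):
        meta = _check_meta(X, meta)
        if self.reference_scope == "qc":
            scope = (meta["type"] == "qc_pool").to_numpy()
        elif self.reference_scope == "study_all":
            scope = (meta["type"] == "study").to_numpy()
        else:
            raise ValueError(f"unknown reference_scope {self.reference_scope!r}")
        if scope.sum() < 1:
            raise ValueError("PQN reference scope contains no injections")
        self.reference_ = X.loc[scope].median(axis=0, skipna=True)
        return self

    def factors(self, X: pd.DataFrame) -> pd.Series:
        ref = self.reference_.to_numpy(float)
        out = np.empty(len(X))
        vals = X.to_numpy(float)
        for i in range(len(X)):
            row = vals[i]
            ok = np.isfinite(row) & np.isfinite(ref) & (ref > 0)
            if ok.sum() < self.min_shared_features:
                raise ValueError(
                    f"injection {X.index[i]!r} shares only {int(ok.sum())} features "
                    f"with the PQN reference (need >= {self.min_shared_features})"
                )
            out[i] = np.median(row[ok] / ref[ok])
        return pd.Series(out, index=X.index, name="pqn_factor")

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        f = self.factors(X)
        self.factors_ = f
        return X.div(f, axis=0)


class LowValueImputer(BaseEstimator, TransformerMixin):
    """Impute left-censored missing values from each injection's low range.

    Missing entries of an injection are drawn uniformly from
    (lower_fraction * m, m) where m is that injection's minimum observed
    value (default window: the lower half of the detection floor).
    """

    def __init__(self, seed: int = 0, lower_fraction: float = 0.5):
        self.seed = seed
        self.lower_fraction = lower_fraction

    def fit(self, X: pd.DataFrame, y=None, **kw):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        rng = np.random.default_rng(self.seed)
        vals = X.to_numpy(float).copy()
        for i in range(vals.shape[0]):
            row = vals[i]
            miss = ~np.isfinite(row)
            if not miss.any():
                continue
            obs = row[~miss]
            if obs.size == 0:
                raise ValueError(f"injection {X.index[i]!r} has no observed values to impute from")
            m = obs.min()
            row[miss] = rng.uniform(self.lower_fraction * m, m, size=int(miss.sum()))
        return pd.DataFrame(vals, index=X.index, columns=X.columns)


class ReplicateAggregator(BaseEstimator, TransformerMixin):
    """Collapse technical replicates to one row per sample.

    Identity for singletons, arithmetic mean for duplicates, median for
    3-4 replicates (and, with a warning, for larger groups).
    """

    def fit(self, X, y=None, **kw):
        return self

    def transform(self, X: pd.DataFrame, *, meta: pd.DataFrame) -> pd.DataFrame:
        meta = _check_meta(X, meta)
        study = (meta["type"] == "study").to_numpy()
        Xs = X.loc[study]
        groups = meta.loc[study, "replicate_group"]
        out = {}
        for gid, idx in groups.groupby(groups).groups.items():
            block = Xs.loc[idx]
            n = len(block)
            if n == 1:
                agg = block.iloc[0]
            elif n == 2:
                agg = block.mean(axis=0)
            else:
                if n > 4:
                    logger.warning("replicate group %r has %d members (> 4); using median", gid, n)
                agg = block.median(axis=0)
            out[gid] = agg
        result = pd.DataFrame(out).T
        result.index.name = "sample_id"
        return result.loc[sorted(out)]


# ---------------------------------------------------------------------------
# functional surface (tables oriented features x injections)


def _t(table: pd.DataFrame) -> pd.DataFrame:
    return table.T


def filter_blank_features(
    table: pd.DataFrame, meta: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, list[str]]:
    cfg = cfg or FilterConfig()
    cfg.validate()
    f = BlankFeatureFilter(cfg.blank_ratio_max).fit(_t(table), meta=meta)
    return _t(f.transform(_t(table))), f.removed_ids_


def filter_dilution_linearity(
    table: pd.DataFrame, meta: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, list[str]]:
    cfg = cfg or FilterConfig()
    cfg.validate()
    f = DilutionLinearityFilter(cfg.dilution_r_min).fit(_t(table), meta=meta)
    return _t(f.transform(_t(table))), f.removed_ids_


def filter_presence(
    table: pd.DataFrame, meta: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, list[str]]:
    cfg = cfg or FilterConfig()
    cfg.validate()
    f = PresenceFilter(cfg.presence_fraction).fit(_t(table), meta=meta)
    return _t(f.transform(_t(table))), f.removed_ids_


def loess_drift_correct(
    table: pd.DataFrame, meta: pd.DataFrame, cfg: LoessConfig | None = None
) -> pd.DataFrame:
    cfg = cfg or LoessConfig()
    cfg.validate()
    c = LoessDriftCorrector(cfg.span, cfg.min_qc_per_batch, cfg.per_batch)
    return _t(c.fit(_t(table), meta=meta).transform(_t(table)))


def pqn_normalize(
    table: pd.DataFrame, meta: pd.DataFrame, reference_scope: str = "qc"
) -> PqnResult:
    norm = PQNNormalizer(reference_scope).fit(_t(table), meta=meta)
    normalized = norm.transform(_t(table))
    return PqnResult(normalized=_t(normalized), factors=norm.factors_, reference=norm.reference_)


def impute_missing(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    return _t(LowValueImputer(seed).fit(_t(table)).transform(_t(table)))


def aggregate_replicates(table: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    return _t(ReplicateAggregator().fit(_t(table)).transform(_t(table), meta=meta))


@dataclass
class ProvenanceLog:
    """Per-stage bookkeeping of the preprocessing pipeline."""

    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, table: pd.DataFrame, **extra) -> None:
        self.stages.append(
            {"stage": stage, "n_features": int(table.shape[0]),
             "n_injections": int(table.shape[1]), **extra}
        )

    def to_jsonl(self) -> str:
        import json

        return "\n".join(json.dumps(s) for s in self.stages)


def run_preprocessing(
    tables: pd.DataFrame | dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    meta: pd.DataFrame | None = None,
    filter_cfg: FilterConfig | None = None,
    loess_cfg: LoessConfig | None = None,
    reference_scope: str = "qc",
    seed: int = 0,
    skip_blank_filter: bool = False,
    skip_dilution_filter: bool = False,
) -> tuple[pd.DataFrame, ProvenanceLog]:
    """Full curation pipeline; returns a features x samples matrix.

    ``tables`` is either one features x injections table (with ``meta``) or a
    mapping mode -> (table, meta); modes are preprocessed independently and
    merged by feature-id concatenation, as for separately acquired HILIC and
    RPLC runs.
    """
    if isinstance(tables, dict):
        log = ProvenanceLog()
        parts = []
        for mode, (tbl, md) in tables.items():
            part, part_log = run_preprocessing(
                tbl, md, filter_cfg, loess_cfg, reference_scope, seed,
                skip_blank_filter, skip_dilution_filter,
            )
            for s in part_log.stages:
                log.stages.append({"mode": mode, **s})
            parts.append(part)
        merged = pd.concat(parts, axis=0)
        if merged.index.duplicated().any():
            raise ValueError("duplicate feature ids across modes; tag ids with their mode")
        log.record("mode_merge", merged)
        return merged, log

    table = tables
    filter_cfg = filter_cfg or FilterConfig()
    loess_cfg = loess_cfg or LoessConfig()
    log = ProvenanceLog()
    log.record("input", table)

    if not skip_blank_filter:
        table, removed = filter_blank_features(table, meta, filter_cfg)
        log.record("blank_filter", table, removed=len(removed))
    # blanks are audit-only: drop them before correction/normalization
    blank_ids = set(meta.loc[meta["type"] == "blank", "injection_id"])
    if blank_ids:
        table = table[[c for c in table.columns if c not in blank_ids]]
    if not skip_dilution_filter:
        table, removed = filter_dilution_linearity(table, meta, filter_cfg)
        log.record("dilution_linearity_filter", table, removed=len(removed))
    table, removed = filter_presence(table, meta, filter_cfg)
    log.record("presence_filter", table, removed=len(removed))
    table = loess_drift_correct(table, meta, loess_cfg)
    log.record("loess_drift_correction", table)
    pqn = pqn_normalize(table, meta, reference_scope)
    table = pqn.normalized
    log.record("pqn", table)
    table = impute_missing(table, seed=seed)
    log.record("imputation", table)
    table = aggregate_replicates(table, meta)
    log.record("replicate_aggregation", table)
    return table, log
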