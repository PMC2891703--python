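"""Phase-I analysis: plate-wise Z-scores and threshold hit calling.

The primary readout is a single inducible firefly-luciferase channel. Each
well's signal is standardised against its own plate — z = (x − plate mean) /
plate SD over all non-empty wells of that plate — which removes plate-scale
effects without any cross-plate fitting. Genes are then called hits when
their z falls below a fixed cutoff (default −2.5) in at least one replicate.

`PlateZScorer` follows the scikit-learn transformer protocol and
`PrimaryHitCaller` the estimator protocol (``get_params``/``set_params``,
fitted attributes with trailing underscores); both operate on the package's
well-level DataFrames rather than feature matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .model import ScreenDataset

HIT, NON_HIT = "hit", "non_hit"


class PlateZScorer(TransformerMixin, BaseEstimator):
    """Standardise luminescence within each plate.

    Parameters
    ----------
    include_controls : bool, default True
        Include control wells in the plate mean/SD ("whole plate"
        convention). Set False to standardise against sample wells only.
    ddof : int, default 1
        Delta degrees of freedom of the plate SD; 1 gives the sample SD.
    channel : str, default "firefly"
        Signal column to standardise.

    Attributes
    ----------
    plate_stats_ : pandas.DataFrame
        Per-plate mean, SD and well count used for the transform.
    """

    def __init__(self, include_controls: bool = True, ddof: int = 1,
                 channel: str = "firefly"):
        self.include_controls = include_controls
        self.ddof = ddof
        self.channel = channel

    def _wells(self, X) -> pd.DataFrame:
        df = X.with_replicate() if isinstance(X, ScreenDataset) else X.copy()
        if "replicate" not in df.columns:
            df["replicate"] = 1
        return df[df["role"] != "empty"]

    def fit(self, X, y=None):
        """Compute per-plate location/scale. X: ScreenDataset or well table."""
        df = self._wells(X)
        basis = df if self.include_controls else df[df["role"] == "sample"]
        stats_ = basis.groupby("plate_id")[self.channel].agg(
            mean="mean", sd=lambda v: v.std(ddof=self.ddof), n="size"
        )
        low = stats_[stats_["n"] < 3]
        if not low.empty:
            raise ValueError(
                f"plate {low.index[0]} has {int(low['n'].iloc[0])} wells; "
                "need >= 3 for a Z-score"
            )
        degenerate = stats_[~(stats_["sd"] > 0)]
        if not degenerate.empty:
            raise ValueError(
                f"plate {degenerate.index[0]} has zero signal SD (degenerate plate)"
            )
        self.plate_stats_ = stats_
        return self

    def transform(self, X) -> pd.DataFrame:
        """Return the non-empty well rows with a ``z`` column appended."""
        df = self._wells(X)
        st = self.plate_stats_
        unknown = set(df["plate_id"]) - set(st.index)
        if unknown:
            raise ValueError(f"plates not seen in fit: {sorted(unknown)}")
        mu = df["plate_id"].map(st["mean"]).to_numpy()
        sd = df["plate_id"].map(st["sd"]).to_numpy()
        out = df.copy()
        out["z"] = (out[self.channel].to_numpy() - mu) / sd
        return out


def plate_zscores(plate: pd.DataFrame | ScreenDataset,
                  include_controls: bool = True, ddof: int = 1) -> pd.DataFrame:
    """Z-score every non-empty well against its plate (fit+transform)."""
    scorer = PlateZScorer(include_controls=include_controls, ddof=ddof)
    return scorer.fit(plate).transform(plate)


def gene_ztable(zwells: pd.DataFrame, reagents: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-replicate Z-scores of sample wells.

    Joins the well-level z values onto the reagent annotation and averages
    wells sharing (gene, replicate) — in a one-amplicon library that is a
    single well. Returns columns gene_id, replicate, z.
    """
    zs = zwells[zwells["role"] == "sample"].merge(
        reagents, left_on="reagent_id", right_on="reagent_id", how="inner"
    )
    return (zs.groupby(["target_gene_id", "replicate"], as_index=False)["z"]
              .mean()
              .rename(columns={"target_gene_id": "gene_id"}))


class PrimaryHitCaller(BaseEstimator):
    """Threshold hit caller on per-gene replicate Z-scores.

    A gene is a hit when its Z-score is strictly below ``cutoff`` in at
    least one replicate (``rule="any"``, the selection actually used to
    build downstream gene lists) or when the replicate mean is below the
    cutoff (``rule="mean"``, matching the averaged scatter-plot view).

    Attributes
    ----------
    calls_ : pandas.DataFrame
        One row per gene: per-replicate z columns, z_mean, label.
    hits_ : list of gene ids labelled ``hit``.
    """

    def __init__(self, cutoff: float = -2.5, rule: str = "any"):
        self.cutoff = cutoff
        self.rule = rule

    def fit(self, X: pd.DataFrame, y=None):
        """X: long table with columns gene_id, replicate, z."""
        if self.rule not in ("any", "mean"):
            raise ValueError(f"rule must be 'any' or 'mean', got {self.rule!r}")
        if X.empty:
            raise ValueError("no Z-scores to call hits on")
        wide = X.pivot_table(index="gene_id", columns="replicate", values="z")
        wide.columns = [f"z_rep{int(c)}" for c in wide.columns]
        zmat = wide.to_numpy()
        if self.rule == "any":
            is_hit = np.nanmin(zmat, axis=1) < self.cutoff
        else:
            is_hit = np.nanmean(zmat, axis=1) < self.cutoff
        calls = wide.reset_index()
        calls["z_mean"] = np.nanmean(zmat, axis=1)
        calls["label"] = np.where(is_hit, HIT, NON_HIT)
        self.calls_ = calls
        self.hits_ = calls.loc[calls["label"] == HIT, "gene_id"].tolist()
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Labels per gene, in the gene order of ``fit`` on X."""
        return self.fit(X).calls_["label"].to_numpy()


def call_primary_hits(ztable: pd.DataFrame, cutoff: float = -2.5,
                      rule: str = "any") -> pd.DataFrame:
    """Call hits from a (gene_id, replicate, z) table; returns ``calls_``."""
    return PrimaryHitCaller(cutoff=cutoff, rule=rule).fit(ztable).calls_


def replicate_correlation(z_rep1, z_rep2) -> float:
    """Pearson correlation of paired per-reagent Z-scores across replicates.

    A screen-quality diagnostic: well-behaved duplicate screens show clear
    positive correlation. Requires n >= 3 pairs and nonzero variance in both
    replicates.
    """
    a = np.asarray(z_rep1, dtype=float)
    b = np.asarray(z_rep2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("replicate vectors must be paired over the same reagents")
    if a.size < 3:
        raise ValueError(f"need >= 3 paired values, got {a.size}")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a replicate; correlation undefined")
    return float(stats.pearsonr(a, b).statistic)
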