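"""Phase II/III analysis: dual-reporter normalisation and classification.

Each well yields an inducible firefly signal and a constitutive Renilla
signal. The firefly/Renilla ratio cancels well- and plate-scale factors
(transfection efficiency, cell number, reader gain); expressing that ratio
as a percentage of the mean ratio of the same plate's negative-control
(GFP dsRNA) wells gives percent-of-control, and

    percent inhibition = 100 − percent of control.

Genes are covered by one or two dsRNA amplicons; replicate wells per
amplicon are averaged, and classification uses the *maximum* amplicon mean
("at least one dsRNA" logic):

* secondary stage — ``group_A`` if max > 75, ``group_B`` if 50 < max ≤ 75,
  ``non_hit`` otherwise;
* tertiary stage — ``positive`` if max > 50, else ``negative``.

Both thresholds are strict. Negative inhibition (activation) is retained in
the tables but can never promote a hit: the screen design detects positive
regulators only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .model import ScreenDataset

SECONDARY_LABELS = ("group_A", "group_B", "non_hit")
TERTIARY_LABELS = ("positive", "negative")


def normalized_activity(firefly: float, renilla: float) -> float:
    """Firefly/Renilla ratio of one well.

    A zero or missing Renilla reading means the constitutive reporter gave
    no signal — a viability or measurement failure — so it is a hard error
    rather than an infinite ratio.
    """
    if renilla is None or np.isnan(renilla) or renilla <= 0:
        raise ValueError(
            f"renilla={renilla!r}: no constitutive signal; well is a "
            "viability/measurement failure, not a ratio of zero"
        )
    return float(firefly) / float(renilla)


def percent_inhibition(sample_ratio: float, control_ratios) -> float:
    """Percent inhibition of one normalised ratio vs plate controls.

    ``100 * (1 - sample_ratio / mean(control_ratios))``; negative values
    (activation above control) are returned as-is, not clipped.
    """
    controls = np.asarray(control_ratios, dtype=float)
    if controls.size == 0 or not np.all(controls > 0):
        raise ValueError("need >= 1 strictly positive control ratio")
    return 100.0 - 100.0 * float(sample_ratio) / float(controls.mean())


def aggregate_replicates(values) -> tuple[float, float, int]:
    """Mean, sample SD (NaN when n < 2) and n of replicate percent values."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no replicate values to aggregate")
    sd = float(np.std(v, ddof=1)) if v.size >= 2 else float("nan")
    return float(v.mean()), sd, int(v.size)


class ReporterNormalizer(TransformerMixin, BaseEstimator):
    """Per-plate percent-inhibition transform for dual-reporter datasets.

    ``fit`` learns each plate's mean negative-control firefly/Renilla ratio;
    ``transform`` returns one row per non-empty, non-failing well with the
    ratio, percent-of-control and percent-inhibition columns appended.

    Parameters
    ----------
    min_renilla : float, default 0
        Wells with Renilla <= this are treated as measurement failures.
        They are dropped with ``on_failure="drop"`` (default) or raise with
        ``on_failure="raise"``.

    Attributes
    ----------
    control_ratio_ : pandas.Series
        Mean GFP-control ratio per plate id.
    n_failed_wells_ : int
        Wells discarded for missing constitutive signal.
    """

    def __init__(self, min_renilla: float = 0.0, on_failure: str = "drop"):
        self.min_renilla = min_renilla
        self.on_failure = on_failure

    def _ratios(self, X) -> pd.DataFrame:
        df = X.with_replicate() if isinstance(X, ScreenDataset) else X.copy()
        if "replicate" not in df.columns:
            df["replicate"] = 1
        df = df[df["role"] != "empty"].copy()
        if df["renilla"].isna().all():
            raise ValueError("dataset has no Renilla channel; dual-reporter "
                             "normalisation needs both reporters")
        failed = ~(df["renilla"] > self.min_renilla)
        if failed.any() and self.on_failure == "raise":
            r = df[failed].iloc[0]
            raise ValueError(
                f"well {r.plate_id}:{r.row}{r.col:02d} has renilla="
                f"{r.renilla}; viability/measurement failure"
            )
        self.n_failed_wells_ = int(failed.sum())
        df = df[~failed].copy()
        df["ratio"] = df["firefly"] / df["renilla"]
        return df

    def fit(self, X, y=None):
        df = self._ratios(X)
        ctrl = df[df["role"] == "negative_control"]
        if ctrl.empty:
            raise ValueError("no negative_control (GFP) wells to normalise against")
        self.control_ratio_ = ctrl.groupby("plate_id")["ratio"].mean()
        return self

    def transform(self, X) -> pd.DataFrame:
        df = self._ratios(X)
        missing = set(df["plate_id"]) - set(self.control_ratio_.index)
        if missing:
            raise ValueError(f"no valid control wells on plate(s) {sorted(missing)}")
        ctrl = df["plate_id"].map(self.control_ratio_).to_numpy()
        df["pct_of_control"] = 100.0 * df["ratio"].to_numpy() / ctrl
        df["pct_inhibition"] = 100.0 - df["pct_of_control"]
        return df


def amplicon_summaries(normalized: pd.DataFrame,
                       reagents: pd.DataFrame) -> pd.DataFrame:
    """Per-amplicon replicate aggregation of percent inhibition.

    Joins normalised sample wells onto the reagent annotation and averages
    replicate wells of each amplicon. Returns columns gene_id,
    amplicon_index, mean_inhibition, sd_inhibition, n.
    """
    sample = normalized[normalized["role"] == "sample"]
    joined = sample.merge(reagents, on="reagent_id", how="inner")
    rows = []
    for (gene, amp), grp in joined.groupby(["target_gene_id", "amplicon_index"]):
        mean, sd, n = aggregate_replicates(grp["pct_inhibition"])
        rows.append((gene, int(amp), mean, sd, n))
    return pd.DataFrame(
        rows, columns=["gene_id", "amplicon_index", "mean_inhibition",
                       "sd_inhibition", "n"],
    )


class InhibitionClassifier(BaseEstimator):
    """Threshold classifier on per-amplicon mean percent inhibition.

    Implements the "at least one dsRNA" rule: a gene is scored on the
    maximum of its amplicon means. Thresholds are strict by default
    (``more than`` 50, ``over`` 75).

    Parameters
    ----------
    stage : {"secondary", "tertiary"}
        Secondary yields group_A / group_B / non_hit; tertiary yields
        positive / negative.
    hit_threshold, strong_threshold : float
        Percent-inhibition cut points (50 and 75).
    inclusive : bool, default False
        If True, genes exactly at a threshold qualify (documented
        alternative reading of the boundary; off by default).

    Attributes
    ----------
    calls_ : pandas.DataFrame
        gene_id, max_inhibition, label — one row per gene, after ``fit``.
    """

    def __init__(self, stage: str = "secondary", hit_threshold: float = 50.0,
                 strong_threshold: float = 75.0, inclusive: bool = False):
        self.stage = stage
        self.hit_threshold = hit_threshold
        self.strong_threshold = strong_threshold
        self.inclusive = inclusive

    def _exceeds(self, value: float, threshold: float) -> bool:
        return value >= threshold if self.inclusive else value > threshold

    def _label(self, max_inhibition: float) -> str:
        if self.stage == "tertiary":
            return ("positive" if self._exceeds(max_inhibition, self.hit_threshold)
                    else "negative")
        if self._exceeds(max_inhibition, self.strong_threshold):
            return "group_A"
        if self._exceeds(max_inhibition, self.hit_threshold):
            return "group_B"
        return "non_hit"

    def fit(self, X: pd.DataFrame, y=None):
        """X: amplicon summary table (gene_id, mean_inhibition, ...)."""
        if self.stage not in ("secondary", "tertiary"):
            raise ValueError(f"stage must be secondary or tertiary, got {self.stage!r}")
        if not 0 < self.hit_threshold < 100:
            raise ValueError("hit_threshold must lie in (0, 100)")
        if X.empty:
            raise ValueError("no amplicon summaries to classify")
        per_gene = (X.dropna(subset=["mean_inhibition"])
                      .groupby("gene_id", sort=False)["mean_inhibition"].max())
        self.calls_ = pd.DataFrame({
            "gene_id": per_gene.index,
            "max_inhibition": per_gene.to_numpy(),
            "label": [self._label(m) for m in per_gene],
        }).reset_index(drop=True)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.fit(X).calls_["label"].to_numpy()


def _summaries_frame(amplicon_means) -> pd.DataFrame:
    """Accept a summary DataFrame or a plain iterable of amplicon means."""
    if isinstance(amplicon_means, pd.DataFrame):
        return amplicon_means
    vals = [float(v) for v in amplicon_means]
    return pd.DataFrame({
        "gene_id": ["gene"] * len(vals),
        "amplicon_index": range(1, len(vals) + 1),
        "mean_inhibition": vals,
    })


def classify_secondary(amplicon_means, **kwargs) -> str:
    """Secondary-stage label for one gene's amplicon mean inhibitions."""
    clf = InhibitionClassifier(stage="secondary", **kwargs)
    return str(clf.fit(_summaries_frame(amplicon_means)).calls_["label"].iloc[0])


def classify_tertiary(amplicon_means, **kwargs) -> str:
    """Tertiary-stage label for one gene's amplicon mean inhibitions."""
    clf = InhibitionClassifier(stage="tertiary", **kwargs)
    return str(clf.fit(_summaries_frame(amplicon_means)).calls_["label"].iloc[0])


def classify_table(table: pd.DataFrame, stage: str = "tertiary",
                   **kwargs) -> pd.DataFrame:
    """Classify a wide per-gene table with ``inhibition_amp{1,2}_mean`` columns.

    This is the layout of the packaged 35-gene fixture: one row per gene,
    up to two amplicon means (second may be NA). Returns gene_id,
    max_inhibition, label.
    """
    mean_cols = [c for c in table.columns
                 if c.startswith("inhibition_amp") and c.endswith("_mean")]
    if not mean_cols:
        raise ValueError("expected inhibition_amp*_mean columns")
    long = table.melt(id_vars=["gene_id"], value_vars=mean_cols,
                      value_name="mean_inhibition").dropna(subset=["mean_inhibition"])
    long["amplicon_index"] = (long["variable"].str.extract(r"amp(\d+)")
                              .astype(int))
    clf = InhibitionClassifier(stage=stage, **kwargs)
    calls = clf.fit(long[["gene_id", "amplicon_index", "mean_inhibition"]]).calls_
    # preserve the input row order
    order = {g: i for i, g in enumerate(table["gene_id"])}
    return calls.sort_values("gene_id", key=lambda s: s.map(order),
                             ignore_index=True)
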