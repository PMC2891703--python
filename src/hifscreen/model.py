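"""Core data model for plate-based reporter screens.

A screen is a set of microtiter plates (96- or 384-well) whose wells carry
dsRNA reagents targeting single genes, plus negative (GFP dsRNA) and positive
(HIF-alpha dsRNA) control wells. Each well yields a firefly-luciferase signal
driven by a hypoxia-responsive enhancer and, in the dual-reporter stages, a
constitutive Renilla-luciferase signal used for normalisation.

Wells live in a flat :class:`pandas.DataFrame` (one row per well) wrapped by
:class:`ScreenDataset`, which adds stage/condition metadata, the plate →
replicate mapping, and invariant validation. All I/O is plain CSV.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: (rows, columns) per supported plate format.
PLATE_FORMATS: dict[int, tuple[int, int]] = {96: (8, 12), 384: (16, 24)}

ROLES = frozenset({"sample", "negative_control", "positive_control", "empty"})
STAGES = frozenset({"primary", "secondary", "tertiary"})
CONDITIONS = frozenset({"DFO", "hypoxia", "normoxia"})

#: Canonical well-table column order used by readers and writers.
WELL_COLUMNS = ["plate_id", "row", "col", "reagent_id", "role", "firefly", "renilla"]


class ScreenFormatError(ValueError):
    """A plate table violates the screen data model."""


def _row_letters(plate_format: int) -> str:
    n_rows, _ = PLATE_FORMATS[plate_format]
    return string.ascii_uppercase[:n_rows]


@dataclass(frozen=True, order=True)
class WellAddress:
    """Position of one well: plate id, row letter, 1-based column."""

    plate_id: str
    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in string.ascii_uppercase[:16]:
            raise ScreenFormatError(f"invalid plate row {self.row!r}")
        if not 1 <= int(self.column) <= 24:
            raise ScreenFormatError(f"invalid plate column {self.column!r}")

    @property
    def label(self) -> str:
        """Zero-padded canonical form, e.g. ``'A01'``; sorts in plate order."""
        return f"{self.row}{self.column:02d}"

    def in_format(self, plate_format: int) -> bool:
        n_rows, n_cols = PLATE_FORMATS[plate_format]
        return self.row in _row_letters(plate_format) and 1 <= self.column <= n_cols


@dataclass(frozen=True)
class Reagent:
    """One dsRNA amplicon silencing one target gene."""

    reagent_id: str
    target_gene_id: str
    amplicon_index: int = 1

    def __post_init__(self) -> None:
        if self.amplicon_index < 1:
            raise ScreenFormatError(
                f"amplicon_index must be >=1, got {self.amplicon_index}"
            )


@dataclass
class ScreenDataset:
    """All wells of one screen stage, across plates and replicates.

    Parameters
    ----------
    wells
        One row per well with columns ``plate_id,row,col,reagent_id,role,
        firefly[,renilla]``. ``reagent_id`` is NA for control/empty wells
        without a library reagent; ``renilla`` is NA when only the firefly
        channel was read.
    stage
        ``primary`` (single reporter), ``secondary`` or ``tertiary`` (dual
        reporter, Renilla required on every non-empty well).
    condition
        Stimulus applied: ``DFO`` (hypoxia mimetic), ``hypoxia`` or
        ``normoxia``.
    replicate_map
        plate_id → replicate index (1-based). Plates sharing a replicate
        index form one pass over the library.
    plate_format
        96 or 384.
    """

    wells: pd.DataFrame
    stage: str = "primary"
    condition: str = "DFO"
    replicate_map: dict[str, int] = field(default_factory=dict)
    plate_format: int = 384

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ScreenFormatError(f"unknown stage {self.stage!r}")
        if self.condition not in CONDITIONS:
            raise ScreenFormatError(f"unknown condition {self.condition!r}")
        if self.plate_format not in PLATE_FORMATS:
            raise ScreenFormatError(f"unsupported plate format {self.plate_format}")
        df = self.wells.copy()
        if "renilla" not in df.columns:
            df["renilla"] = np.nan
        missing = [c for c in WELL_COLUMNS if c not in df.columns]
        if missing:
            raise ScreenFormatError(f"well table missing columns {missing}")
        df = df[WELL_COLUMNS].reset_index(drop=True)
        df["reagent_id"] = df["reagent_id"].where(df["reagent_id"].notna(), np.nan)
        df["col"] = df["col"].astype(int)
        df["firefly"] = df["firefly"].astype(float)
        df["renilla"] = df["renilla"].astype(float)
        self.wells = df
        if not self.replicate_map:
            self.replicate_map = {p: 1 for p in df["plate_id"].unique()}
        hard = _hard_violations(self)
        if hard:
            raise ScreenFormatError("; ".join(hard))

    @property
    def plate_ids(self) -> list[str]:
        return list(dict.fromkeys(self.wells["plate_id"]))

    @property
    def n_replicates(self) -> int:
        return len(set(self.replicate_map.values()))

    def plate(self, plate_id: str) -> pd.DataFrame:
        """Well rows of one plate."""
        sub = self.wells[self.wells["plate_id"] == plate_id]
        if sub.empty:
            raise KeyError(f"no plate {plate_id!r} in dataset")
        return sub

    def sample_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["role"] == "sample"]

    def with_replicate(self) -> pd.DataFrame:
        """Well table plus a ``replicate`` column from the replicate map."""
        out = self.wells.copy()
        out["replicate"] = out["plate_id"].map(self.replicate_map)
        return out


def _hard_violations(ds: ScreenDataset) -> list[str]:
    """Violations that make a dataset unusable (raised at construction)."""
    df = ds.wells
    out: list[str] = []
    bad_role = sorted(set(df["role"]) - ROLES)
    if bad_role:
        out.append(f"unknown role(s) {bad_role}")
    for chan in ("firefly", "renilla"):
        neg = df[df[chan] < 0]
        if not neg.empty:
            r = neg.iloc[0]
            out.append(
                f"negative {chan} luminescence at {r.plate_id}:{r.row}{r.col:02d}"
            )
    dup = df.duplicated(subset=["plate_id", "row", "col"], keep=False)
    if dup.any():
        r = df[dup].iloc[0]
        out.append(f"duplicate well address {r.row}{r.col:02d} on plate {r.plate_id}")
    return out


def validate_dataset(ds: ScreenDataset) -> list[str]:
    """Check every dataset invariant; return human-readable violations.

    An empty list means the dataset is well formed. Hard structural problems
    (duplicate addresses, negative signal, unknown roles) are raised already
    at construction; this reports the softer contract violations: wells
    outside the declared plate format, sample wells with no reagent, missing
    Renilla in dual-reporter stages, and replicates not covering the same
    reagent set.
    """
    violations = list(_hard_violations(ds))
    df = ds.wells
    letters = _row_letters(ds.plate_format)
    _, n_cols = PLATE_FORMATS[ds.plate_format]
    off = df[~(df["row"].isin(list(letters)) & df["col"].between(1, n_cols))]
    for _, r in off.iterrows():
        violations.append(
            f"well {r.row}{r.col:02d} on plate {r.plate_id} outside "
            f"{ds.plate_format}-well format"
        )
    orphan = df[(df["role"] == "sample") & df["reagent_id"].isna()]
    for _, r in orphan.iterrows():
        violations.append(
            f"sample well {r.plate_id}:{r.row}{r.col:02d} has no reagent_id"
        )
    if ds.stage in ("secondary", "tertiary"):
        nonempty = df[df["role"] != "empty"]
        miss = nonempty[nonempty["renilla"].isna()]
        for _, r in miss.iterrows():
            violations.append(
                f"{ds.stage} stage requires renilla: missing at "
                f"{r.plate_id}:{r.row}{r.col:02d}"
            )
    unmapped = set(df["plate_id"]) - set(ds.replicate_map)
    for p in sorted(unmapped):
        violations.append(f"plate {p} missing from replicate_map")
    if not unmapped:
        samples = ds.with_replicate()
        samples = samples[samples["role"] == "sample"].dropna(subset=["reagent_id"])
        per_rep = samples.groupby("replicate")["reagent_id"].agg(set)
        if len(per_rep) > 1:
            union: set[str] = set().union(*per_rep)
            for rep, seen in per_rep.items():
                for reagent in sorted(union - seen):
                    violations.append(
                        f"reagent {reagent} absent from replicate {rep}"
                    )
    return violations


def read_plate_table(path, plate_format: int = 384, stage: str = "primary",
                     condition: str = "DFO",
                     replicate_map: dict[str, int] | None = None) -> ScreenDataset:
    """Read a well-level CSV into a validated :class:`ScreenDataset`.

    The file must carry a header with ``plate_id,row,col,reagent_id,role,
    firefly`` and optionally ``renilla``. Row count is conserved: every CSV
    row becomes exactly one well.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "row": str, "reagent_id": str})
    required = [c for c in WELL_COLUMNS if c != "renilla"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScreenFormatError(f"{path}: missing required columns {missing}")
    ds = ScreenDataset(
        wells=df, stage=stage, condition=condition,
        replicate_map=replicate_map or {}, plate_format=plate_format,
    )
    hard = [v for v in validate_dataset(ds) if "outside" in v or "no reagent_id" in v]
    if hard:
        raise ScreenFormatError(f"{path}: " + "; ".join(hard))
    return ds


def write_plate_table(ds: ScreenDataset, path) -> None:
    """Write the well table as CSV in canonical column order (lossless)."""
    ds.wells.to_csv(path, index=False)


def read_reagent_table(path) -> pd.DataFrame:
    """Read a reagent annotation CSV: reagent_id,target_gene_id,amplicon_index."""
    df = pd.read_csv(path, dtype={"reagent_id": str, "target_gene_id": str})
    missing = [c for c in ("reagent_id", "target_gene_id") if c not in df.columns]
    if missing:
        raise ScreenFormatError(f"{path}: missing required columns {missing}")
    if "amplicon_index" not in df.columns:
        df["amplicon_index"] = 1
    df["amplicon_index"] = df["amplicon_index"].astype(int)
    if (df["amplicon_index"] < 1).any():
        raise ScreenFormatError(f"{path}: amplicon_index must be >= 1")
    dup = df.duplicated(subset=["target_gene_id", "amplicon_index"], keep=False)
    if dup.any():
        r = df[dup].iloc[0]
        raise ScreenFormatError(
            f"{path}: duplicate amplicon_index {r.amplicon_index} "
            f"for gene {r.target_gene_id}"
        )
    return df[["reagent_id", "target_gene_id", "amplicon_index"]]
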