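"""Downstream quantification: relative qPCR expression and kinetic β-gal.

qPCR follows the comparative-Ct (Livak) scheme with tubulin as the
reference transcript: technical triplicates are averaged on the Ct scale,
ΔCt = mean Ct(target) − mean Ct(reference), and relative expression between
a sample and a control condition is 2^−(ΔCt_sample − ΔCt_control). The
exponent base is exactly 2, i.e. 100% amplification efficiency, which both
target and reference reactions approach on standard curves; an efficiency-
corrected base is available as a keyword.

β-galactosidase activity is quantified from a CPRG colour-development time
course read at 574 nm: the heat-inactivated background series is subtracted
point-wise, an ordinary least-squares line is fitted to corrected OD vs
time, and activity is slope per µg of protein. The fit R² doubles as the
linearity check — low R² flags the result rather than failing it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def delta_ct(ct_target, ct_reference) -> float:
    """ΔCt: mean target Ct minus mean reference Ct (replicates averaged on
    the Ct scale). Scalars or replicate iterables accepted."""
    t = np.atleast_1d(np.asarray(ct_target, dtype=float))
    r = np.atleast_1d(np.asarray(ct_reference, dtype=float))
    if t.size == 0 or r.size == 0 or np.isnan(t).any() or np.isnan(r).any():
        raise ValueError("missing Ct value(s)")
    return float(t.mean() - r.mean())


def fold_induction(delta_ct_sample: float, delta_ct_control: float,
                   base: float = 2.0) -> float:
    """Relative expression ``base ** -(ΔCt_sample − ΔCt_control)``.

    ``base=2`` assumes 100% amplification efficiency; pass ``1 + E`` for an
    efficiency-corrected estimate.
    """
    return float(base ** -(float(delta_ct_sample) - float(delta_ct_control)))


def relative_expression(ct_table: pd.DataFrame, control_sample: str,
                        reference_gene: str = "tubulin",
                        base: float = 2.0) -> pd.DataFrame:
    """Fold induction per (sample, target gene) from a long Ct table.

    ``ct_table`` columns: sample_id, gene, ct (a replicate column is
    optional; replicates are averaged). Every sample must include the
    reference gene; every target present in the control sample is reported
    relative to it.
    """
    for c in ("sample_id", "gene", "ct"):
        if c not in ct_table.columns:
            raise ValueError(f"Ct table missing column {c!r}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycle numbers")
    mean_ct = ct_table.groupby(["sample_id", "gene"])["ct"].mean()
    samples = ct_table["sample_id"].unique()
    dcts: dict[tuple[str, str], float] = {}
    for s in samples:
        per_gene = mean_ct.loc[s]
        if reference_gene not in per_gene.index:
            raise ValueError(f"sample {s!r} lacks reference gene {reference_gene!r}")
        ref = per_gene[reference_gene]
        for gene, ct in per_gene.items():
            if gene != reference_gene:
                dcts[(s, gene)] = delta_ct(ct, ref)
    if control_sample not in samples:
        raise ValueError(f"control sample {control_sample!r} not in Ct table")
    rows = []
    for (s, gene), d in dcts.items():
        key = (control_sample, gene)
        if key not in dcts and s != control_sample:
            raise ValueError(
                f"control sample lacks gene {gene!r}; no ΔΔCt reference"
            )
        control_d = dcts.get(key, d)
        rows.append((s, gene, d, d - control_d,
                     fold_induction(d, control_d, base=base)))
    return pd.DataFrame(
        rows, columns=["sample_id", "gene", "delta_ct", "delta_delta_ct", "fold"]
    )


@dataclass
class BgalResult:
    """Kinetic β-galactosidase activity with its fit diagnostics."""

    activity: float        # ΔOD574 · min⁻¹ · µg⁻¹
    slope: float           # ΔOD574 · min⁻¹, background-corrected
    intercept: float
    r_squared: float
    protein_ug: float
    linearity_warning: bool


def bgal_activity(time_min, od574, od574_background, protein_ug: float,
                  r2_threshold: float = 0.9) -> BgalResult:
    """β-gal activity from a background-subtracted OD574 time course.

    Subtracts the heat-inactivated background point-wise (the grids must
    match exactly), fits OLS corrected-OD vs time, and divides the slope by
    the protein input. R² below ``r2_threshold`` sets a linearity warning
    flag on the result.
    """
    t = np.asarray(time_min, dtype=float)
    od = np.asarray(od574, dtype=float)
    bg = np.asarray(od574_background, dtype=float)
    if t.size < 2:
        raise ValueError("need >= 2 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    if od.shape != t.shape:
        raise ValueError("od574 and time grids differ in length")
    if bg.shape != t.shape:
        raise ValueError("background series not on the same time grid")
    if protein_ug <= 0:
        raise ValueError(f"protein_ug must be > 0, got {protein_ug}")
    corrected = od - bg
    fit = stats.linregress(t, corrected)
    # r-value is 0/undefined for a flat series; a zero slope is a valid result
    r2 = float(fit.rvalue ** 2) if not np.isnan(fit.rvalue) else 1.0
    if np.allclose(corrected, corrected[0]):
        r2 = 1.0
    return BgalResult(
        activity=float(fit.slope) / float(protein_ug),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        protein_ug=float(protein_ug),
        linearity_warning=bool(r2 < r2_threshold),
    )
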