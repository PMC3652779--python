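"""Plate/day correction and phenotype summarization.

Raw well concentrations are first divided by culture optical density
(OD600), then corrected for technical day and plate effects estimated from
the control wells only, and finally summarized per mutant strain into a
gene x element phenotype ``D`` with a replicate-scale estimate ``sigma~``.

The correction is a control-anchored surrogate for a linear mixed-effects
normalization: per element, on the log scale,

    day effect   (fixed)   = mean of the day's control wells - grand control mean
    plate effect (shrunk)  = lambda * (plate control mean - day mean)

where the shrinkage factor ``lambda = B / (B + W/n)`` is the classic
empirical-Bayes weight built from the between-plate variance ``B`` of the
control plate-means (method-of-moments, floored at zero) and the pooled
within-plate control variance ``W`` with ``n`` controls per plate.  Plates
are then corrected by subtracting (day + plate) on the log scale, i.e.
dividing by ``exp(correction)`` on the measurement scale, so phenotypes
stay in linear concentration units.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import CONTROL, MUTANT, ElementPanel, RawScreenSet

__all__ = [
    "PlateCorrection",
    "PhenotypeTable",
    "od_normalize",
    "fit_plate_correction",
    "apply_correction",
    "summarize_phenotypes",
]


def od_normalize(raw: RawScreenSet) -> RawScreenSet:
    """Divide every concentration by the well's OD600; metadata untouched."""
    od = raw.data["od600"].to_numpy(dtype=float)
    bad = ~(od > 0)
    if bad.any():
        well = raw.data.loc[raw.data.index[bad][0], "well"]
        plate = raw.data.loc[raw.data.index[bad][0], "plate_id"]
        raise ValidationError(
            f"od600 must be positive; offending well {well} on plate {plate}"
        )
    out = raw.data.copy()
    for e in raw.panel:
        out[e] = out[e].to_numpy(dtype=float) / od
    return RawScreenSet(out, raw.panel)


@dataclass
class PlateCorrection:
    """Additive log-scale corrections per plate and element."""

    corrections: pd.DataFrame  # index plate_id, columns elements
    standard_errors: pd.DataFrame  # same shape; rough se of each correction
    shrinkage: pd.Series = field(default=None)  # per-element lambda

    def for_plate(self, plate_id: str) -> pd.Series:
        return self.corrections.loc[plate_id]


def fit_plate_correction(raw_odnorm: RawScreenSet) -> PlateCorrection:
    """Estimate per-plate log-scale corrections from control wells.

    Every plate must carry at least one control well.  An element whose
    control values show no variance at all yields zero corrections with a
    warning (nothing to estimate).
    """
    df = raw_odnorm.data
    controls = df[df["role"] == CONTROL]
    plates = df["plate_id"].unique().tolist()
    missing = [p for p in plates if p not in set(controls["plate_id"])]
    if missing:
        raise ValidationError(
            f"plate(s) without any control well: {', '.join(missing)}"
        )
    day_of_plate = (
        df.drop_duplicates("plate_id").set_index("plate_id")["run_id"].to_dict()
    )

    corr = pd.DataFrame(0.0, index=plates, columns=list(raw_odnorm.panel.names))
    se = pd.DataFrame(0.0, index=plates, columns=corr.columns)
    lam = pd.Series(0.0, index=corr.columns)

    for e in raw_odnorm.panel:
        vals = controls[e].to_numpy(dtype=float)
        if not (vals > 0).all():
            raise ValidationError(
                f"non-positive control concentration for element {e}; "
                "log-scale correction undefined"
            )
        logv = np.log(vals)
        if np.ptp(logv) == 0.0:
            warnings.warn(
                f"element {e}: zero variance among control wells; "
                "corrections set to 0",
                stacklevel=2,
            )
            continue
        grand = logv.mean()
        by_plate = controls.groupby("plate_id")[e]
        plate_mean = by_plate.apply(
            lambda s: np.log(s.to_numpy(dtype=float)).mean()
        )
        # pooled within-plate variance of log controls
        wvars = by_plate.apply(
            lambda s: np.log(s.to_numpy(dtype=float)).var(ddof=1)
            if len(s) > 1 else np.nan
        )
        W = 0.0 if wvars.isna().all() else float(np.nanmean(wvars.to_numpy()))
        n_bar = float(controls.groupby("plate_id")[e].size().mean())

        day_mean = {}
        for d, sub in controls.groupby("run_id"):
            day_mean[d] = np.log(sub[e].to_numpy(dtype=float)).mean()
        day_eff = {d: m - grand for d, m in day_mean.items()}

        resid = {
            p: float(plate_mean[p]) - grand - day_eff[day_of_plate[p]]
            for p in plates
        }
        rvals = np.array(list(resid.values()))
        B_raw = rvals.var(ddof=1) if len(rvals) > 1 else 0.0
        B = max(B_raw - (W / n_bar if n_bar > 0 else 0.0), 0.0)
        denom = B + (W / n_bar if n_bar > 0 else 0.0)
        shrink = B / denom if denom > 0 else 0.0
        lam[e] = shrink

        n_day = controls.groupby("run_id")[e].size().to_dict()
        for p in plates:
            d = day_of_plate[p]
            corr.loc[p, e] = day_eff[d] + shrink * resid[p]
            n_p = len(by_plate.get_group(p))
            se.loc[p, e] = np.sqrt(
                W / max(n_day[d], 1) + (shrink ** 2) * W / max(n_p, 1)
            )
    return PlateCorrection(corr, se, lam)


def apply_correction(
    raw_odnorm: RawScreenSet, correction: PlateCorrection
) -> RawScreenSet:
    """Divide each well by exp(plate correction) for its plate."""
    missing = set(raw_odnorm.data["plate_id"]) - set(correction.corrections.index)
    if missing:
        raise ValidationError(
            f"corrections missing for plate(s): {', '.join(sorted(missing))}"
        )
    out = raw_odnorm.data.copy()
    factors = np.exp(
        correction.corrections.loc[out["plate_id"]].to_numpy(dtype=float)
    )
    elements = list(raw_odnorm.panel.names)
    out[elements] = out[elements].to_numpy(dtype=float) / factors
    return RawScreenSet(out, raw_odnorm.panel)


@dataclass
class PhenotypeTable:
    """Normalized gene x element phenotypes with replicate-level values.

    ``D`` is the mean of the corrected replicate values (linear scale);
    ``sigma_tilde`` their sample standard deviation (n-1 denominator).
    Genes with a single replicate cannot provide a scale estimate and are
    listed in ``flagged_single_rep`` (excluded from significance testing);
    cells with zero replicate spread are listed in ``zero_scale``.
    """

    D: pd.DataFrame  # index gene, columns elements
    sigma_tilde: pd.DataFrame
    replicate_values: pd.DataFrame  # long: gene_id, element, replicate, value
    panel: ElementPanel
    flagged_single_rep: frozenset[str] = frozenset()

    @property
    def genes(self) -> list[str]:
        return list(self.D.index)

    @property
    def zero_scale(self) -> set[tuple[str, str]]:
        z = self.sigma_tilde.to_numpy() == 0.0
        return {
            (self.sigma_tilde.index[i], self.sigma_tilde.columns[j])
            for i, j in zip(*np.where(z))
        }

    def replicate_matrix(self, element: str) -> pd.DataFrame:
        """Wide replicate table for one element (rows genes, cols replicate)."""
        sub = self.replicate_values[self.replicate_values["element"] == element]
        return sub.pivot(index="gene_id", columns="replicate", values="value")


def summarize_phenotypes(
    raw_odnorm: RawScreenSet, correction: PlateCorrection
) -> PhenotypeTable:
    """Correct plate effects, then summarize each mutant over its replicates."""
    corrected = apply_correction(raw_odnorm, correction)
    mut = corrected.data[corrected.data["role"] == MUTANT]
    elements = list(raw_odnorm.panel.names)

    long = mut.melt(
        id_vars=["strain_id", "replicate"],
        value_vars=elements,
        var_name="element",
        value_name="value",
    ).rename(columns={"strain_id": "gene_id"})

    counts = mut.groupby("strain_id").size()
    single = frozenset(counts.index[counts < 2])
    if single:
        warnings.warn(
            f"{len(single)} gene(s) with a single replicate flagged and "
            "excluded from significance testing",
            stacklevel=2,
        )

    grp = long.groupby(["gene_id", "element"])["value"]
    D = grp.mean().unstack()[elements]
    sigma = grp.std(ddof=1).unstack()[elements]
    genes = sorted(set(D.index) - single)
    return PhenotypeTable(
        D=D.loc[genes],
        sigma_tilde=sigma.loc[genes],
        replicate_values=long[~long["gene_id"].isin(single)].reset_index(drop=True),
        panel=raw_odnorm.panel,
        flagged_single_rep=single,
    )
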