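"""Plate-wise Z-score hit calling against the in-plate DMSO null.

A compound well is a hit when all three gates pass, with strict
inequalities (boundary values are non-hits):

* fold > 2 (default) — the target transcript is more than doubled;
* ddCt Z-score < -2 — the shift is outside the vehicle-noise envelope,
  where Z = ddCt / SD(dCt over the 32 DMSO wells) (ddCt is a constant
  shift of dCt, so their SDs coincide);
* -10 < calibrator-Ct Z < 10 — the housekeeping gene itself did not move,
  guarding against wells where apparent induction is a normalization
  artifact (e.g. compound toxicity suppressing the calibrator).

Hits are called per plate, never pooled across plates; replicate plates
are reconciled at the campaign level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import DmsoReference
from .plate import CtTable, PlateMap

RULE_BOTH = "both"
RULE_ANY = "any"
REPLICATE_RULES = (RULE_BOTH, RULE_ANY)


class DegenerateNullError(ValueError):
    """The DMSO null has zero spread; Z-scores are undefined."""


@dataclass(frozen=True)
class HitThresholds:
    """The triple hit criterion's cutoffs."""

    min_fold: float = 2.0
    max_ddct_z: float = -2.0
    calibrator_z_bound: float = 10.0

    def __post_init__(self) -> None:
        if not self.min_fold > 1:
            raise ValueError(f"min_fold must be > 1, got {self.min_fold}")
        if not self.max_ddct_z < 0:
            raise ValueError(f"max_ddct_z must be < 0, got {self.max_ddct_z}")
        if not self.calibrator_z_bound > 0:
            raise ValueError(f"calibrator_z_bound must be > 0, got {self.calibrator_z_bound}")


def ddct_zscores(relative_expressions: pd.DataFrame, reference: DmsoReference) -> pd.Series:
    """Per-well Z = ddct / SD(dCt of DMSO wells).

    The DMSO ddct mean is 0 by construction, so no re-centering is needed.
    """
    if reference.sd_delta_ct <= 0:
        raise DegenerateNullError(
            f"plate {reference.plate_id}: DMSO dCt SD is {reference.sd_delta_ct}; "
            "Z-scores undefined"
        )
    z = relative_expressions["ddct"] / reference.sd_delta_ct
    z.name = "ddct_z"
    return z


def calibrator_ct_zscores(
    ct_table: CtTable,
    plate_map: PlateMap,
    calibrator_gene: str,
    reference: DmsoReference,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> pd.Series:
    """Per-well Z of the raw calibrator Ct against the DMSO calibrator null."""
    if reference.sd_calibrator_ct <= 0:
        raise DegenerateNullError(
            f"plate {reference.plate_id}: DMSO calibrator Ct SD is "
            f"{reference.sd_calibrator_ct}; Z-scores undefined"
        )
    if calibrator_gene != reference.calibrator_gene:
        raise ValueError(
            f"calibrator mismatch: {calibrator_gene!r} vs reference "
            f"{reference.calibrator_gene!r}"
        )
    piv = ct_table.ct_pivot()
    if calibrator_gene not in piv.columns:
        raise ValueError(f"gene {calibrator_gene!r} not on plate {ct_table.plate_id}")
    populated = [str(w) for w in plate_map.populated_wells()]
    cal = piv.loc[piv.index.isin(populated) & ~piv.index.isin(exclude), calibrator_gene].dropna()
    z = (cal - reference.mean_calibrator_ct) / reference.sd_calibrator_ct
    z.name = "calibrator_ct_z"
    return z


def call_hits(
    relative_expressions: pd.DataFrame,
    ddct_z: pd.Series,
    calibrator_z: pd.Series,
    thresholds: HitThresholds = HitThresholds(),
    plate_map: PlateMap | None = None,
) -> pd.DataFrame:
    """Apply the triple criterion per well.

    Returns one row per well present in all inputs, with the three Z/fold
    quantities, the individual pass flags and their conjunction ``is_hit``.
    When ``plate_map`` is given, compound identity and concentration are
    attached (empty for DMSO wells).
    """
    wells = relative_expressions.index.intersection(ddct_z.index).intersection(
        calibrator_z.index
    )
    fold = relative_expressions.loc[wells, "fold"]
    z = ddct_z.loc[wells]
    cz = calibrator_z.loc[wells]
    if not (np.isfinite(z).all() and np.isfinite(cz).all() and np.isfinite(fold).all()):
        raise ValueError("non-finite fold or Z-score input to call_hits")
    out = pd.DataFrame(
        {
            "fold": fold,
            "ddct_z": z,
            "calibrator_ct_z": cz,
            "pass_fold": fold > thresholds.min_fold,
            "pass_z": z < thresholds.max_ddct_z,
            "pass_calibrator": (cz > -thresholds.calibrator_z_bound)
            & (cz < thresholds.calibrator_z_bound),
        }
    )
    out["is_hit"] = out["pass_fold"] & out["pass_z"] & out["pass_calibrator"]
    if plate_map is not None:
        contents = {str(w): c for w, c in plate_map.wells.items()}
        out.insert(0, "compound_id", [
            (contents[w].compound_id or "") if w in contents else "" for w in out.index
        ])
        out.insert(1, "concentration_uM", [
            contents[w].concentration_um if w in contents else None for w in out.index
        ])
        out.insert(2, "kind", [contents[w].kind if w in contents else "" for w in out.index])
    out.index.name = "well"
    out.attrs.update(relative_expressions.attrs)
    return out


def reconcile_replicates(
    hit_calls_by_replicate: Mapping[str, pd.DataFrame],
    rule: str = RULE_BOTH,
) -> pd.DataFrame:
    """Reconcile per-plate hit calls into campaign-level compound calls.

    ``rule='both'`` (default, conservative): a compound is a campaign hit
    iff it is a hit in every replicate it appears in; ``rule='any'``: in at
    least one.  Returns a frame indexed by compound_id with replicate
    bookkeeping columns and ``campaign_hit``.
    """
    if rule not in REPLICATE_RULES:
        raise ValueError(f"unknown replicate rule {rule!r}; expected one of {REPLICATE_RULES}")
    rows: list[dict] = []
    for replicate_id, calls in hit_calls_by_replicate.items():
        if "compound_id" not in calls.columns:
            raise ValueError(f"replicate {replicate_id!r}: hit calls lack compound_id")
        sub = calls[calls["compound_id"].astype(str) != ""]
        for rec in sub.itertuples(index=False):
            rows.append(
                {
                    "compound_id": rec.compound_id,
                    "replicate": replicate_id,
                    "is_hit": bool(rec.is_hit),
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["n_replicates", "n_hits", "rule", "campaign_hit"]
        ).rename_axis("compound_id")
    long = pd.DataFrame(rows)
    grouped = long.groupby("compound_id")["is_hit"].agg(n_replicates="size", n_hits="sum")
    grouped["rule"] = rule
    if rule == RULE_BOTH:
        grouped["campaign_hit"] = grouped["n_hits"] == grouped["n_replicates"]
    else:
        grouped["campaign_hit"] = grouped["n_hits"] >= 1
    return grouped
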