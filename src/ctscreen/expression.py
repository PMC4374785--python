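"""Livak relative quantification: per-well dCt, ddCt against the in-plate
DMSO vehicle reference, and fold change 2^-ddCt.

Sign convention (Livak): dCt = Ct_target - Ct_calibrator per well, and
ddCt = dCt_well - mean(dCt over DMSO wells), so *up*-regulation of the
target gives negative ddCt and fold = 2^-ddCt > 1.  The DMSO-well ddCt
population has mean 0 by construction, which is what makes the plate-wise
Z-score hit gate well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate import CtTable, PlateMap

_MAD_SCALE = 1.4826  # consistency factor: MAD -> SD under a Gaussian


class ExpressionError(ValueError):
    """Invalid input to relative-quantification operations."""


@dataclass(frozen=True)
class DmsoReference:
    """Per-plate vehicle null statistics for one target/calibrator pair.

    Means and sample (n-1) standard deviations are computed over the DMSO
    wells only — the 32 vehicle wells of the screening design.
    """

    plate_id: str
    target_gene: str
    calibrator_gene: str
    mean_delta_ct: float
    sd_delta_ct: float
    mean_calibrator_ct: float
    sd_calibrator_ct: float
    n_wells: int

    def __post_init__(self) -> None:
        if self.n_wells < 2:
            raise ExpressionError(f"DMSO reference needs >= 2 wells, got {self.n_wells}")
        if self.sd_delta_ct < 0 or self.sd_calibrator_ct < 0:
            raise ExpressionError("reference SDs must be >= 0")


def delta_ct(
    ct_table: CtTable,
    target_gene: str,
    calibrator_gene: str,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> pd.DataFrame:
    """Per-well dCt = Ct_target - Ct_calibrator.

    Wells missing either gene are omitted with a warning; wells in
    ``exclude`` (e.g. flagged by plate validation) are dropped silently.
    Returns a frame indexed by canonical well, with columns ``ct_target``,
    ``ct_calibrator``, ``target_censored`` and ``delta_ct``; the gene pair
    and plate id travel in ``DataFrame.attrs``.
    """
    if target_gene == calibrator_gene:
        raise ExpressionError("target and calibrator genes must differ")
    piv = ct_table.ct_pivot()
    cens = ct_table.censored_pivot()
    for gene in (target_gene, calibrator_gene):
        if gene not in piv.columns:
            raise ExpressionError(f"gene {gene!r} not measured on plate {ct_table.plate_id}")
    keep = piv.index[~piv.index.isin(exclude)]
    both = piv.loc[keep, [target_gene, calibrator_gene]].dropna()
    n_missing = len(keep) - len(both)
    if n_missing:
        warnings.warn(
            f"plate {ct_table.plate_id}: {n_missing} well(s) missing "
            f"{target_gene} or {calibrator_gene}; omitted",
            stacklevel=2,
        )
    if both.empty:
        raise ExpressionError(
            f"no well on plate {ct_table.plate_id} carries both "
            f"{target_gene} and {calibrator_gene}"
        )
    out = pd.DataFrame(
        {
            "ct_target": both[target_gene],
            "ct_calibrator": both[calibrator_gene],
            "target_censored": cens.loc[both.index, target_gene].astype(bool),
            "delta_ct": both[target_gene] - both[calibrator_gene],
        }
    )
    out.index.name = "well"
    out.attrs.update(
        plate_id=ct_table.plate_id,
        target_gene=target_gene,
        calibrator_gene=calibrator_gene,
    )
    return out


def dmso_reference(
    plate_map: PlateMap,
    delta_cts: pd.DataFrame,
    robust: bool = False,
) -> DmsoReference:
    """Vehicle-null statistics over the plate's DMSO wells.

    ``delta_cts`` is the output of :func:`delta_ct` (it carries the per-well
    calibrator Ct needed for the calibrator-drift gate).  With
    ``robust=True`` the location/scale are median and Gaussian-scaled MAD
    instead of mean/SD (a non-default variant for artifact-heavy plates).
    """
    if plate_map.plate_id != delta_cts.attrs.get("plate_id"):
        raise ExpressionError(
            f"plate id mismatch: map {plate_map.plate_id!r} vs "
            f"delta_cts {delta_cts.attrs.get('plate_id')!r}"
        )
    dmso = [str(w) for w in plate_map.dmso_wells()]
    sub = delta_cts.loc[delta_cts.index.intersection(dmso)]
    if len(sub) < 2:
        raise ExpressionError(
            f"plate {plate_map.plate_id}: need >= 2 DMSO wells with valid dCt, got {len(sub)}"
        )
    dct = sub["delta_ct"].to_numpy(float)
    cal = sub["ct_calibrator"].to_numpy(float)
    if robust:
        loc_d, loc_c = float(np.median(dct)), float(np.median(cal))
        scale_d = _MAD_SCALE * float(np.median(np.abs(dct - loc_d)))
        scale_c = _MAD_SCALE * float(np.median(np.abs(cal - loc_c)))
    else:
        loc_d, loc_c = float(np.mean(dct)), float(np.mean(cal))
        scale_d = float(np.std(dct, ddof=1))
        scale_c = float(np.std(cal, ddof=1))
    return DmsoReference(
        plate_id=plate_map.plate_id,
        target_gene=delta_cts.attrs["target_gene"],
        calibrator_gene=delta_cts.attrs["calibrator_gene"],
        mean_delta_ct=loc_d,
        sd_delta_ct=scale_d,
        mean_calibrator_ct=loc_c,
        sd_calibrator_ct=scale_c,
        n_wells=len(sub),
    )


def ddct_fold(delta_cts: pd.DataFrame, reference: DmsoReference) -> pd.DataFrame:
    """Add ddCt and fold = 2^-ddCt columns against the DMSO reference.

    The reference must come from the same plate and gene pair; fold is
    exactly 2**(-ddct), so a one-cycle drop of the target Ct doubles fold.
    """
    for key, ref_val in (
        ("plate_id", reference.plate_id),
        ("target_gene", reference.target_gene),
        ("calibrator_gene", reference.calibrator_gene),
    ):
        if delta_cts.attrs.get(key) != ref_val:
            raise ExpressionError(
                f"reference mismatch on {key}: {delta_cts.attrs.get(key)!r} vs {ref_val!r}"
            )
    out = delta_cts.copy()
    out["ddct"] = out["delta_ct"] - reference.mean_delta_ct
    out["fold"] = 2.0 ** (-out["ddct"])
    out.attrs.update(delta_cts.attrs)
    return out
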