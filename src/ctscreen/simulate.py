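"""Ground-truth simulators for every pipeline stage, plus truth-based
screen evaluation.

The generators emulate the screening campaign's design: 384-well plates
with 32 in-plate DMSO vehicle wells, every compound plated in duplicate at
a single 12 µM screening dose, well-level Gaussian Ct noise, additive
per-plate per-gene Ct offsets (to which ddCt is provably invariant), and
active compounds whose target-gene Ct drops by log2(fold) where fold comes
from the compound's own 4PL curve evaluated at the plated dose.  The
calibrator gene is untouched by compound effects unless an off-target
shift is requested, which exercises the calibrator-drift hit gate.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .doseresponse import DoseResponseData, four_pl
from .plate import (
    DEFAULT_MAX_CYCLES,
    KIND_COMPOUND,
    KIND_DMSO,
    N_COLS,
    ROW_LETTERS,
    CtTable,
    PlateMap,
    WellAddress,
    WellContent,
)

# DMSO vehicle wells occupy the two rightmost columns: 16 rows x 2 = 32 wells
DMSO_COLUMNS = (23, 24)
COMPOUND_WELLS_PER_PLATE = len(ROW_LETTERS) * (N_COLS - len(DMSO_COLUMNS))  # 352

DEFAULT_BASELINE_CT = {"TRIB1": 24.0, "GAPDH": 18.0}
DEFAULT_SCREENING_DOSE_UM = 12.0
DEFAULT_ACTIVE_EC50_UM = 2.3
DEFAULT_ACTIVE_HILL = 1.2
DEFAULT_ACTIVE_FOLD = 3.5


class SimulationError(ValueError):
    """Inconsistent simulation parameters."""


@dataclass(frozen=True)
class NoiseModel:
    """Noise magnitudes for the Ct and dose-response generators.

    sigma_ct: well-level Gaussian SD on each Ct measurement (cycles).
    plate_shift_sd: SD of the additive per-plate, per-gene Ct offset
        (cycles) modeling batch/instrument drift.
    dr_cv: coefficient of variation of the multiplicative lognormal noise
        on dose-response fold values.
    """

    sigma_ct: float = 0.25
    plate_shift_sd: float = 0.5
    dr_cv: float = 0.10

    def __post_init__(self) -> None:
        if min(self.sigma_ct, self.plate_shift_sd, self.dr_cv) < 0:
            raise SimulationError("noise magnitudes must be >= 0")


@dataclass(frozen=True)
class CompoundEffect:
    """An active compound's dose-response truth on its target gene."""

    compound_id: str
    gene: str
    top_fold: float
    ec50_um: float = DEFAULT_ACTIVE_EC50_UM
    hill: float = DEFAULT_ACTIVE_HILL

    def fold_at(self, dose_um: float) -> float:
        return float(four_pl(dose_um, 1.0, self.top_fold, self.ec50_um, self.hill))


@dataclass
class SimulationTruth:
    """Everything needed to regenerate and score a simulated campaign."""

    seed: int
    target_gene: str = "TRIB1"
    calibrator_gene: str = "GAPDH"
    baseline_ct: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE_CT))
    effects: dict[str, CompoundEffect] = field(default_factory=dict)
    plate_compounds: list[list[str]] = field(default_factory=list)
    screening_dose_um: float = DEFAULT_SCREENING_DOSE_UM
    n_dmso: int = 32
    calibrator_shift_ct: float = 0.0  # optional off-target shift on compound wells

    @property
    def all_compounds(self) -> set[str]:
        return {c for plate in self.plate_compounds for c in plate}

    def active_compounds(self) -> set[str]:
        return {
            cid
            for cid, eff in self.effects.items()
            if eff.fold_at(self.screening_dose_um) > 1.0
        }

    def fold_at_screen(self, compound_id: str) -> float:
        eff = self.effects.get(compound_id)
        return eff.fold_at(self.screening_dose_um) if eff is not None else 1.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid in sorted(self.all_compounds):
            eff = self.effects.get(cid)
            rows.append(
                {
                    "compound_id": cid,
                    "active": eff is not None,
                    "fold_at_screen": self.fold_at_screen(cid),
                    "top_fold": eff.top_fold if eff else 1.0,
                    "ec50_um": eff.ec50_um if eff else np.nan,
                    "hill": eff.hill if eff else np.nan,
                }
            )
        return pd.DataFrame(rows)


def _plate_layout() -> tuple[list[WellAddress], list[WellAddress]]:
    """(compound wells row-major, DMSO wells) for the fixed 384-well layout."""
    compound = [
        WellAddress(r, c)
        for r in ROW_LETTERS
        for c in range(1, N_COLS + 1)
        if c not in DMSO_COLUMNS
    ]
    dmso = [WellAddress(r, c) for r in ROW_LETTERS for c in DMSO_COLUMNS]
    return compound, dmso


def simulate_ct_plate(
    truth: SimulationTruth,
    noise: NoiseModel,
    plate_index: int,
    seed: int,
    max_cycles: float = DEFAULT_MAX_CYCLES,
) -> tuple[PlateMap, CtTable]:
    """One simulated 384-well plate (map + Ct table).

    ``plate_index`` addresses the duplicate layout: compound set
    ``plate_index // 2``, replicate ``plate_index % 2``.  DMSO wells get
    Ct = baseline + plate shift + well noise; compound wells additionally
    shift the target Ct by -log2(fold at the screening dose).  Ct values
    are censored at ``max_cycles``.  Deterministic for fixed arguments.
    """
    n_sets = len(truth.plate_compounds)
    if not 0 <= plate_index < 2 * n_sets:
        raise SimulationError(f"plate_index {plate_index} outside 0..{2 * n_sets - 1}")
    set_index, replicate = divmod(plate_index, 2)
    compounds = truth.plate_compounds[set_index]
    compound_wells, dmso_wells = _plate_layout()
    if len(compounds) > len(compound_wells):
        raise SimulationError("more compounds than compound wells")

    plate_id = f"SET{set_index + 1:03d}-R{replicate + 1}"
    wells: dict[WellAddress, WellContent] = {}
    for well, cid in zip(compound_wells, compounds):
        wells[well] = WellContent(KIND_COMPOUND, cid, truth.screening_dose_um)
    for well in dmso_wells:
        wells[well] = WellContent(KIND_DMSO)
    plate_map = PlateMap(plate_id, wells)

    rng = np.random.default_rng([seed, plate_index])
    genes = [truth.target_gene, truth.calibrator_gene]
    plate_shift = {g: rng.normal(0.0, noise.plate_shift_sd) for g in genes}

    records: list[dict] = []
    for well in sorted(wells):
        content = wells[well]
        fold = truth.fold_at_screen(content.compound_id) if content.kind == KIND_COMPOUND else 1.0
        for gene in genes:
            ct = truth.baseline_ct[gene] + plate_shift[gene] + rng.normal(0.0, noise.sigma_ct)
            if gene == truth.target_gene and fold != 1.0:
                ct -= np.log2(fold)
            if (
                gene == truth.calibrator_gene
                and content.kind == KIND_COMPOUND
                and truth.calibrator_shift_ct
                and content.compound_id in truth.effects
            ):
                ct += truth.calibrator_shift_ct
            censored = ct >= max_cycles
            records.append(
                {
                    "well": str(well),
                    "gene": gene,
                    "ct": float(max_cycles) if censored else float(ct),
                    "censored": bool(censored),
                }
            )
    data = pd.DataFrame(records, columns=["well", "gene", "ct", "censored"])
    return plate_map, CtTable(plate_id, data, max_cycles=float(max_cycles))


def simulate_campaign(
    n_plates: int,
    active_fraction: float,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    fold_distribution: float | Callable[[np.random.Generator], float] = DEFAULT_ACTIVE_FOLD,
    ec50_um: float = DEFAULT_ACTIVE_EC50_UM,
    hill: float = DEFAULT_ACTIVE_HILL,
    target_gene: str = "TRIB1",
    calibrator_gene: str = "GAPDH",
    calibrator_shift_ct: float = 0.0,
) -> tuple[list[tuple[PlateMap, CtTable]], SimulationTruth]:
    """A duplicate-plated screening campaign with known ground truth.

    ``n_plates`` distinct 352-compound sets are each plated twice (at the
    12 µM screening dose), giving ``2 * n_plates`` plates.  A deterministic
    fraction of compounds is active; each active's screening-dose fold is
    drawn from ``fold_distribution`` (a constant or a callable on the rng)
    and back-converted to a 4PL top so that fold_at(12 µM) equals the drawn
    value.
    """
    if not 0.0 <= active_fraction <= 1.0:
        raise SimulationError(f"active_fraction {active_fraction} outside [0, 1]")
    n_compounds = n_plates * COMPOUND_WELLS_PER_PLATE
    ids = [f"CPD{i + 1:05d}" for i in range(n_compounds)]
    rng = np.random.default_rng([seed, 0xC0FFEE])
    n_active = int(round(active_fraction * n_compounds))
    active_ids = sorted(rng.choice(ids, size=n_active, replace=False))

    saturation = 1.0 / (1.0 + (ec50_um / DEFAULT_SCREENING_DOSE_UM) ** hill)
    effects: dict[str, CompoundEffect] = {}
    for cid in active_ids:
        fold = fold_distribution(rng) if callable(fold_distribution) else float(fold_distribution)
        if fold <= 0:
            raise SimulationError("active fold must be > 0")
        top = 1.0 + (fold - 1.0) / saturation
        effects[cid] = CompoundEffect(cid, target_gene, top, ec50_um, hill)

    plate_compounds = [
        ids[i * COMPOUND_WELLS_PER_PLATE : (i + 1) * COMPOUND_WELLS_PER_PLATE]
        for i in range(n_plates)
    ]
    baselines = dict(DEFAULT_BASELINE_CT)
    baselines.setdefault(target_gene, 24.0)
    baselines.setdefault(calibrator_gene, 18.0)
    truth = SimulationTruth(
        seed=seed,
        target_gene=target_gene,
        calibrator_gene=calibrator_gene,
        baseline_ct=baselines,
        effects=effects,
        plate_compounds=plate_compounds,
        calibrator_shift_ct=calibrator_shift_ct,
    )
    plates = [
        simulate_ct_plate(truth, noise, plate_index, seed)
        for plate_index in range(2 * n_plates)
    ]
    return plates, truth


def simulate_dose_response(
    params: tuple[float, float, float, float],
    doses: Sequence[float],
    n_replicates: int = 3,
    dr_cv: float = 0.10,
    seed: int = 0,
    compound_id: str = "CPD00001",
    gene: str = "TRIB1",
) -> DoseResponseData:
    """Replicate fold measurements from a 4PL truth curve.

    ``params`` is (bottom, top, ec50, hill).  Each point is
    4PL(dose) x a mean-one lognormal factor with coefficient of variation
    ``dr_cv`` (exact curve values when ``dr_cv`` is 0).
    """
    bottom, top, ec50_um, hill = params
    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any():
        raise SimulationError("doses must be positive")
    rng = np.random.default_rng([seed, 0xD05E])
    curve = four_pl(doses, bottom, top, ec50_um, hill)
    rows = []
    sigma = np.sqrt(np.log1p(dr_cv**2))
    for replicate in range(1, n_replicates + 1):
        if dr_cv > 0:
            factor = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=doses.size))
        else:
            factor = np.ones_like(doses)
        for dose, fold in zip(doses, curve * factor):
            rows.append({"dose_um": dose, "fold": fold, "replicate": replicate})
    return DoseResponseData(compound_id, gene, pd.DataFrame(rows))


def simulate_profiles(
    n_genes: int,
    groups: Sequence[str] = ("inducer", "inhibitor"),
    marker_spec: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 0.25,
    seed: int = 0,
    n_replicates: int = 3,
    timepoint: str = "6h",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-group expression profiles with spiked marker genes.

    Genes are ``G0001..``; ``marker_spec`` maps gene -> {group: LFC}
    giving that gene the stated log2 fold change versus vehicle in that
    group's samples (0 elsewhere).  Baseline log2 intensities are uniform
    on [4, 12]; replicate noise is Gaussian on the log2 scale with SD
    ``noise_sd``.  Returns an intensity matrix (genes x samples) and the
    matching treatment design.
    """
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    marker_spec = marker_spec or {}
    unknown = set(marker_spec) - set(genes)
    if unknown:
        raise SimulationError(f"marker_spec names unknown genes: {sorted(unknown)}")
    for gene, per_group in marker_spec.items():
        bad = set(per_group) - set(groups)
        if bad:
            raise SimulationError(f"marker_spec[{gene!r}] names unknown groups: {sorted(bad)}")

    rng = np.random.default_rng([seed, 0xF00D])
    baseline = rng.uniform(4.0, 12.0, size=n_genes)
    design_rows: list[dict] = []
    columns: dict[str, np.ndarray] = {}
    for rep in range(1, n_replicates + 1):
        sample = f"DMSO_{timepoint}_r{rep}"
        columns[sample] = baseline + rng.normal(0.0, noise_sd, size=n_genes)
        design_rows.append(
            {"sample": sample, "treatment": "DMSO", "dose": np.nan,
             "timepoint": timepoint, "replicate": rep, "is_vehicle": True}
        )
    for group in groups:
        shift = np.zeros(n_genes)
        for gene, per_group in marker_spec.items():
            if group in per_group:
                shift[genes.index(gene)] = per_group[group]
        for rep in range(1, n_replicates + 1):
            sample = f"{group}_{timepoint}_r{rep}"
            columns[sample] = baseline + shift + rng.normal(0.0, noise_sd, size=n_genes)
            design_rows.append(
                {"sample": sample, "treatment": group, "dose": np.nan,
                 "timepoint": timepoint, "replicate": rep, "is_vehicle": False}
            )
    matrix = pd.DataFrame(
        {s: 2.0**v for s, v in columns.items()}, index=pd.Index(genes, name="gene")
    )
    design = pd.DataFrame(design_rows).set_index("sample")
    return matrix, design


@dataclass(frozen=True)
class ScreenMetrics:
    """Truth-based campaign performance summary."""

    recall: float
    false_discovery_rate: float
    per_plate_hit_counts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.recall <= 1.0 and 0.0 <= self.false_discovery_rate <= 1.0):
            raise SimulationError("recall and FDR must lie in [0, 1]")


def evaluate_screen(
    campaign_hits: pd.DataFrame,
    truth: SimulationTruth | pd.DataFrame,
    per_plate_hit_counts: Sequence[int] = (),
) -> ScreenMetrics:
    """Score campaign-level hit calls against simulation truth.

    ``campaign_hits`` is the replicate-reconciliation output (indexed by
    compound_id with a ``campaign_hit`` column).  ``truth`` is a
    :class:`SimulationTruth` or its ``to_frame()`` CSV round-trip.  Recall
    is TP / number of true actives (1.0 when there are none to find); FDR
    is FP / max(1, number of called hits), so an empty call set scores 0.
    """
    if isinstance(truth, SimulationTruth):
        universe = truth.all_compounds
        actives = truth.active_compounds()
    else:
        if not {"compound_id", "fold_at_screen"}.issubset(truth.columns):
            raise SimulationError("truth frame needs compound_id and fold_at_screen")
        universe = set(truth["compound_id"])
        actives = set(truth.loc[truth["fold_at_screen"] > 1.0, "compound_id"])
    called = set(campaign_hits.index[campaign_hits["campaign_hit"].astype(bool)])
    stray = set(campaign_hits.index) - universe
    if stray:
        raise SimulationError(f"campaign compounds unknown to truth: {sorted(stray)[:5]}")
    tp = len(called & actives)
    fp = len(called - actives)
    recall = tp / len(actives) if actives else 1.0
    fdr = fp / max(1, len(called))
    return ScreenMetrics(recall, fdr, tuple(int(c) for c in per_plate_hit_counts))
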