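"""End-to-end orchestration: validate -> ddCt -> Z-scores -> hit calls ->
replicate reconciliation, plus the confirmation stage (4PL fits and the
minimal-effective-concentration matrix), with a JSON run manifest.

Runs are deterministic: re-running with unchanged inputs, config and seed
reproduces byte-identical stage outputs, and the manifest records a SHA-256
digest for every file it reads or writes.
"""

from __future__ import annotations

import hashlib
import json
import sys
import warnings
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .doseresponse import DoseResponseData, fit_4pl, minimal_effective_concentration
from .expression import DmsoReference, ddct_fold, delta_ct, dmso_reference
from .hits import (
    HitThresholds,
    calibrator_ct_zscores,
    call_hits,
    ddct_zscores,
    reconcile_replicates,
)
from .plate import CtTable, PlateMap, read_ct_table, read_plate_map, validate_plate

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_STAGE = 3


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Analysis configuration; validated up front and serialized verbatim
    into the run manifest."""

    target_gene: str = "TRIB1"
    calibrator_gene: str = "GAPDH"
    thresholds: HitThresholds = field(default_factory=HitThresholds)
    replicate_rule: str = "both"
    max_cycles: float = 55.0
    min_dmso: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.thresholds, Mapping):
            self.thresholds = HitThresholds(**self.thresholds)
        if self.target_gene == self.calibrator_gene:
            raise ValueError("target and calibrator genes must differ")
        if self.replicate_rule not in ("both", "any"):
            raise ValueError(f"unknown replicate rule {self.replicate_rule!r}")
        if not self.max_cycles > 0:
            raise ValueError("max_cycles must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Machine-readable provenance record for one pipeline run."""

    config: dict
    config_digest: str
    seed: int
    versions: dict
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    stages: list[str] = field(default_factory=list)
    created: str = ""

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _versions() -> dict:
    import scipy

    return {
        "ctscreen": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "python": sys.version.split()[0],
    }


def screen_plate(
    plate_map: PlateMap, ct_table: CtTable, config: RunConfig
) -> tuple[pd.DataFrame, DmsoReference]:
    """Run the full per-plate screening analysis; raise PipelineError with
    the failing stage's name on any defect."""
    try:
        report = validate_plate(
            plate_map,
            ct_table,
            required_genes=(config.target_gene, config.calibrator_gene),
            min_dmso=config.min_dmso,
            calibrator_gene=config.calibrator_gene,
        )
    except Exception as exc:
        raise PipelineError("validate", str(exc)) from exc
    if not report.ok:
        raise PipelineError("validate", "; ".join(report.errors))
    exclude = report.excluded_wells
    try:
        dcts = delta_ct(ct_table, config.target_gene, config.calibrator_gene, exclude=exclude)
        reference = dmso_reference(plate_map, dcts)
        rel = ddct_fold(dcts, reference)
    except Exception as exc:
        raise PipelineError("ddct", str(exc)) from exc
    try:
        z = ddct_zscores(rel, reference)
        cal_z = calibrator_ct_zscores(
            ct_table, plate_map, config.calibrator_gene, reference, exclude=exclude
        )
    except Exception as exc:
        raise PipelineError("zscores", str(exc)) from exc
    try:
        hits = call_hits(rel, z, cal_z, config.thresholds, plate_map)
    except Exception as exc:
        raise PipelineError("hits", str(exc)) from exc
    return hits, reference


def run_screen_pipeline(
    config: RunConfig,
    plates: Sequence[tuple[PlateMap, CtTable] | tuple[str | Path, str | Path]],
    out_dir: str | Path,
) -> RunManifest:
    """Screen every plate, reconcile replicates, write outputs + manifest.

    ``plates`` holds either in-memory (PlateMap, CtTable) pairs or
    (plate_map_csv, ct_table_csv) path pairs.  Writes per-plate hit CSVs,
    a campaign CSV keyed by compound_id, and ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        config_digest=config.digest(),
        seed=config.seed,
        versions=_versions(),
        created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    hit_frames: dict[str, pd.DataFrame] = {}
    for item in plates:
        first, second = item
        if isinstance(first, (str, Path)):
            map_path, ct_path = Path(first), Path(second)
            # plate-map CSVs carry no intrinsic id; derive it from the file
            # name, tolerating a `<plate>_map.csv` naming convention
            stem = map_path.stem
            for suffix in ("_map", ".map"):
                if stem.endswith(suffix):
                    stem = stem[: -len(suffix)]
            try:
                plate_map = read_plate_map(map_path, plate_id=stem)
                ct_table = read_ct_table(ct_path, max_cycles=config.max_cycles)
            except Exception as exc:
                raise PipelineError("read", str(exc)) from exc
            manifest.inputs[map_path.name] = _sha256(map_path)
            manifest.inputs[ct_path.name] = _sha256(ct_path)
        else:
            plate_map, ct_table = first, second
        hits, _ = screen_plate(plate_map, ct_table, config)
        hit_frames[plate_map.plate_id] = hits
        out_path = out_dir / f"{plate_map.plate_id}_hits.csv"
        hits.assign(plate_id=plate_map.plate_id, config_digest=config.digest()).to_csv(out_path)
        manifest.outputs[out_path.name] = _sha256(out_path)
    manifest.stages.extend(["validate", "ddct", "zscores", "hits"])
    try:
        campaign = reconcile_replicates(hit_frames, rule=config.replicate_rule)
    except Exception as exc:
        raise PipelineError("reconcile", str(exc)) from exc
    manifest.stages.append("reconcile")
    campaign_path = out_dir / "campaign_hits.csv"
    campaign.assign(config_digest=config.digest()).to_csv(campaign_path)
    manifest.outputs[campaign_path.name] = _sha256(campaign_path)
    manifest.to_json(out_dir / "manifest.json")
    return manifest


def run_confirmation(
    config: RunConfig,
    dose_datasets: Iterable[DoseResponseData],
    hit_compounds: Sequence[str] = (),
    threshold_fold: float = 2.0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confirmation stage: per-series 4PL fits and the MEC summary matrix.

    Returns (fits, mec) frames.  ``fits`` has one row per fit-attempted
    series; ``mec`` is compound x gene with cells like ``"1.5"`` or
    ``"IA [1.6]"``.  Hit compounds that lack dose data get a warning (and a
    row with no fit), never an abort.
    """
    fit_rows: list[dict] = []
    mec_cells: dict[tuple[str, str], str] = {}
    seen: set[str] = set()
    for data in dose_datasets:
        seen.add(data.compound_id)
        fit = fit_4pl(data)
        fit_rows.append(
            {
                "compound_id": data.compound_id,
                "gene": data.gene,
                "bottom": fit.bottom,
                "top": fit.top,
                "ec50_um": fit.ec50,
                "hill": fit.hill,
                "rss": fit.rss,
                "converged": fit.converged,
                "ec50_in_range": fit.ec50_in_range,
                "n_points": fit.n_points,
            }
        )
        mec = minimal_effective_concentration(data, threshold_fold)
        mec_cells[(data.compound_id, data.gene)] = mec.cell()
    for cid in hit_compounds:
        if cid not in seen:
            warnings.warn(f"hit compound {cid} has no dose-response data", stacklevel=2)
            fit_rows.append({"compound_id": cid, "gene": "", "converged": False})
    fits = pd.DataFrame(fit_rows)
    if mec_cells:
        mec_frame = (
            pd.Series(mec_cells).rename_axis(["compound_id", "gene"]).unstack("gene")
        )
    else:
        mec_frame = pd.DataFrame()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fits.to_csv(out_dir / "fourpl_fits.csv", index=False)
        mec_frame.to_csv(out_dir / "mec_matrix.csv")
    return fits, mec_frame


def read_dose_response_csv(path: str | Path) -> list[DoseResponseData]:
    """Load dose-response series from the confirmation-stage CSV
    (``compound_id,gene,dose_uM,fold,replicate``), one series per
    (compound, gene)."""
    frame = pd.read_csv(path)
    required = {"compound_id", "gene", "dose_uM", "fold", "replicate"}
    missing = required - set(frame.columns)
    if missing:
        raise PipelineError("read", f"{Path(path).name}: missing columns {sorted(missing)}")
    out = []
    for (cid, gene), sub in frame.groupby(["compound_id", "gene"]):
        points = sub.rename(columns={"dose_uM": "dose_um"})[["dose_um", "fold", "replicate"]]
        out.append(DoseResponseData(str(cid), str(gene), points.reset_index(drop=True)))
    return out
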