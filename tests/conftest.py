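"""Shared fixtures: tiny hand-built plates and seeded synthetic data."""

import numpy as np
import pandas as pd
import pytest

from ctscreen.plate import CtTable, PlateMap, WellAddress, WellContent
from ctscreen.simulate import NoiseModel, simulate_campaign, simulate_ct_plate

EIGHT_DOSES = 25.0 / 2.0 ** np.arange(8)  # 2-fold dilutions from 25 uM


def make_ct_table(plate_id, entries, max_cycles=55.0):
    """entries: iterable of (well, gene, ct[, censored])."""
    rows = []
    for entry in entries:
        well, gene, ct, *rest = entry
        rows.append(
            {"well": well, "gene": gene, "ct": float(ct),
             "censored": bool(rest[0]) if rest else False}
        )
    return CtTable(plate_id, pd.DataFrame(rows), max_cycles=max_cycles)


def make_plate_map(plate_id, dmso_wells, compound_wells, dose_um=12.0):
    """compound_wells: mapping well-string -> compound id."""
    wells = {WellAddress.parse(w): WellContent("dmso") for w in dmso_wells}
    for w, cid in compound_wells.items():
        wells[WellAddress.parse(w)] = WellContent("compound", cid, dose_um)
    return PlateMap(plate_id, wells)


@pytest.fixture
def tiny_plate():
    """4 DMSO wells + 2 compound wells, both genes everywhere, no noise
    beyond hand-chosen offsets.  CPDUP is induced ~4-fold (target Ct two
    cycles down); CPDNULL sits on the vehicle distribution."""
    dmso = ["A01", "A02", "A03", "A04"]
    pmap = make_plate_map("P1", dmso, {"B01": "CPDUP", "B02": "CPDNULL"})
    entries = []
    dmso_dct = [5.8, 6.2, 5.9, 6.1]
    for w, dct in zip(dmso, dmso_dct):
        entries += [(w, "GAPDH", 18.0), (w, "TRIB1", 18.0 + dct)]
    entries += [("B01", "GAPDH", 18.0), ("B01", "TRIB1", 22.0)]   # dCt 4 -> fold 4
    entries += [("B02", "GAPDH", 18.0), ("B02", "TRIB1", 24.05)]  # dCt 6.05 ~ null
    return pmap, make_ct_table("P1", entries)


@pytest.fixture
def simulated_plate():
    """One full 384-well plate with default noise and a few known actives."""
    plates, truth = simulate_campaign(
        n_plates=1, active_fraction=0.05, noise=NoiseModel(), seed=11
    )
    plate_map, ct_table = plates[0]
    return plate_map, ct_table, truth
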