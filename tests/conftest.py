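"""Shared fixtures: a held-out null-HC run and the full default-cohort run.

Both are session-scoped because they carry the expensive manifold fits; all
data is generated programmatically by the package's own cohort simulator.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from gmltwin import (
    CohortConfig,
    DigitalTwinModel,
    RiskStratifier,
    build_features,
    generate_cohort,
    pseudotime_scores,
)

logging.getLogger("gmltwin").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def null_run():
    """500 reference HC + 100 held-out HC, no disease effects: the null
    calibration bed for GeoNorm z-scores."""
    cfg = CohortConfig(seed=1, n_reference=600, n_per_group=0)
    records, volumes = generate_cohort(cfg)
    ref_mask = np.zeros(len(records), bool)
    ref_mask[:500] = True
    table = build_features(volumes, records, reference_mask=ref_mask)
    model = DigitalTwinModel(
        table.subset(ref_mask), records.loc[ref_mask, "age"].to_numpy(),
        k=30, random_state=7,
    ).fit()
    held = table.subset(~ref_mask)
    dev = model.score(held, records.loc[~ref_mask, "age"].to_numpy())
    return dict(config=cfg, records=records, table=table, ref_mask=ref_mask,
                model=model, dev=dev)


@pytest.fixture(scope="session")
def default_run():
    """The default planted cohort (1000 reference + 3 x 152 clinical),
    scored and risk-stratified: the parameter-recovery bed."""
    cfg = CohortConfig(seed=11)
    records, volumes = generate_cohort(cfg)
    table = build_features(volumes, records)
    ref_mask = (records["cohort"] == "reference").to_numpy()
    model = DigitalTwinModel(
        table.subset(ref_mask), records.loc[ref_mask, "age"].to_numpy(),
        k=30, random_state=5,
    ).fit()
    clin_mask = ~ref_mask
    clinical = table.subset(clin_mask)
    dev = model.score(clinical, records.loc[clin_mask, "age"].to_numpy(),
                      groups=records.loc[clin_mask, "group"].to_numpy())
    groups = dev.profiles["group"].to_numpy()
    is_ris = np.isin(groups, ["RIS-NC", "RIS-C"])
    ris = records.loc[clin_mask].loc[is_ris].reset_index(drop=True)
    strat = RiskStratifier(
        dev.z_roi.to_numpy()[is_ris], ris["converted"].to_numpy(dtype=bool),
        subject_ids=list(ris["subject_id"]), k_clusters=4, n_boot=500, seed=3,
    ).fit()
    coords = model.transform(clinical.values)
    scores, graph_k = pseudotime_scores(coords, groups == "HC",
                                        subject_ids=clinical.subject_ids)
    return dict(config=cfg, records=records, table=table, model=model, dev=dev,
                groups=groups, is_ris=is_ris, ris=ris, strat=strat,
                scores=scores, graph_k=graph_k)
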