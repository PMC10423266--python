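"""Shared fixtures.

The heavy session fixtures (``strong_run``, ``null_run``) generate phantom
cohorts and train desk-profile CNNs once per session; they are only built
when a test actually requests them.
"""

from __future__ import annotations

import numpy as np
import pytest

from petmip import outcome_cnn
from petmip.cli import RunConfig, prepare_cohort_data
from petmip.cohort_sampling import build_subsets
from petmip.evaluation import fit_calibration


def stack_pairs(mips_variant: dict, ids) -> tuple[np.ndarray, np.ndarray]:
    xc = np.stack([mips_variant[p]["coronal"].pixels[..., None] for p in ids]).astype(np.float32)
    xs = np.stack([mips_variant[p]["sagittal"].pixels[..., None] for p in ids]).astype(np.float32)
    return xc, xs


@pytest.fixture(scope="session")
def small_cohort():
    """30 phantoms with the default outcome model and all MIP variants."""
    cfg = RunConfig(n_patients=30, seed=3, outcome="default")
    records, mips, feats, geom = prepare_cohort_data(
        cfg, ("mip", "brain_removed", "lesion", "lesion_mask"))
    return {"records": records, "mips": mips, "features": feats,
            "geometry": geom, "config": cfg}


@pytest.fixture(scope="session")
def strong_run():
    """Strong-signal benchmark: 200 phantoms, desk-profile training of fold 0
    of subset A under two schemes — the lesion-MIP scheme (signal recovery)
    and the mask->BR-MIP transfer scheme (ablation and plausibility)."""
    cfg = RunConfig(n_patients=200, seed=1, outcome="strong", scheme="br_mip")
    records, mips, feats, geom = prepare_cohort_data(
        cfg, ("lesion", "lesion_mask", "brain_removed"))
    partition = build_subsets(records, seed=cfg.seed)
    mc = outcome_cnn.ModelConfig.desk(seed=cfg.seed)

    lesion_models, _ = outcome_cnn.train_scheme_lesion(
        partition, "A", mips["lesion"], mc, folds=[0])
    lesion_model = lesion_models[0]
    brmip_models, _ = outcome_cnn.train_scheme_transfer(
        partition, "A", mips["lesion_mask"], mips["brain_removed"], mc, folds=[0])
    brmip_model = brmip_models[0]

    labels = {r.patient_id: r.label for r in records}
    tr_ids, va_ids = partition.folds["A"][0]
    held_ids = [r.patient_id for r in records if r.patient_id not in set(tr_ids)]

    def predict_ids(model, variant, ids):
        xc, xs = stack_pairs(mips[variant], ids)
        return model.model.predict_proba(xc, xs)[:, 1]

    y_val = np.array([labels[p] for p in va_ids])
    y_held = np.array([labels[p] for p in held_ids])
    p_val_brmip = predict_ids(brmip_model, "brain_removed", va_ids)
    calibration = fit_calibration(p_val_brmip, y_val)
    return {
        "config": cfg, "records": records, "mips": mips, "features": feats,
        "geometry": geom, "partition": partition, "labels": labels,
        "lesion_model": lesion_model, "brmip_model": brmip_model,
        "train_ids": tr_ids, "val_ids": va_ids, "held_ids": held_ids,
        "y_val": y_val, "y_held": y_held,
        "p_held_lesion": predict_ids(lesion_model, "lesion", held_ids),
        "p_val_brmip": p_val_brmip,
        "p_held_brmip": predict_ids(brmip_model, "brain_removed", held_ids),
        "calibration": calibration,
    }


@pytest.fixture(scope="session")
def null_run():
    """No-signal control: 100 phantoms with image-independent labels, the
    lesion scheme trained on a stratified 80/20 split."""
    from sklearn.model_selection import train_test_split

    cfg = RunConfig(n_patients=100, seed=5, outcome="null", scheme="lesion")
    records, mips, feats, _ = prepare_cohort_data(cfg, ("lesion", "lesion_mask"))
    ids = [r.patient_id for r in records]
    labels = {r.patient_id: r.label for r in records}
    y = np.array([labels[p] for p in ids])
    tr, va = train_test_split(ids, test_size=0.2, stratify=y, random_state=cfg.seed)
    mc = outcome_cnn.ModelConfig.desk(seed=cfg.seed)
    model = outcome_cnn.DualBranchCNN(mc)
    xc, xs = stack_pairs(mips["lesion"], tr)
    model.fit(xc, xs, np.array([labels[p] for p in tr]), epochs=mc.epochs_stage1)
    vxc, vxs = stack_pairs(mips["lesion"], va)
    p_val = model.predict_proba(vxc, vxs)[:, 1]
    y_val = np.array([labels[p] for p in va])
    return {"p_val": p_val, "y_val": y_val, "model": model, "config": cfg}
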