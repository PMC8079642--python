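"""End-to-end orchestration: preprocess → STFM → CCEP → features → models.

``synthetic_patient_features`` runs the whole chain on one synthetic
patient and returns the per-pair feature table together with the ground
truth, which is what the recovery experiments and the cohort evaluation
build on. ``evaluate_patient``/``evaluate_cohort`` fit the model
variants with stratified 5-fold CV.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import ccep as ccep_mod
from . import netfeat
from .model import MODEL_FEATURES, cohort_comparison, fit_cv, summarize_cohort
from .preprocess import preprocess_session
from .session import Session
from .stfm import HighGammaExtractor, epoch_hg, significance_map
from .synth import SynthConfig, generate_spes_session, generate_task_session


def analyze_task_session(
    session: Session,
    q: float = 0.05,
    window_ms: tuple = (-1000.0, 2000.0),
    mad_factor: float = 5.0,
    preprocessed: bool = False,
):
    """Preprocess (bad channels, 1 kHz, CAR), extract HG, map significance.

    Returns ``(hg_series, significance_map, session)`` where the HG
    series covers every channel (bad channels are carried through but
    forced STFM− downstream).
    """
    if not preprocessed:
        session = preprocess_session(session, mad_factor=mad_factor, car=True)
    ext = HighGammaExtractor(sample_rate=session.sample_rate)
    log_power = ext.transform(session.signals)
    centers = ext.bin_centers_ms(session.n_samples)
    hg = epoch_hg(
        log_power, centers, session.events["onset_ms"].to_numpy(), window_ms
    )
    sig_map = significance_map(hg, q=q)
    bad = ~session.good_mask
    sig_map.stfm_positive[bad] = False
    sig_map.fdr_mask[bad] = False
    return hg, sig_map, session


def analyze_spes_session(
    session: Session, pair: str, mad_factor: float = 5.0, z_threshold: float = 6.0
):
    """Preprocess (no CAR; see methods note) and score CCEPs for one pair."""
    session = preprocess_session(session, mad_factor=mad_factor, car=False)
    return ccep_mod.analyze_pair(session, pair, z_threshold=z_threshold)


def synthetic_patient_features(
    config: SynthConfig,
    q: float = 0.05,
    z_threshold: float = 6.0,
    damping: float = 0.85,
    variance_fraction: float = 0.8,
):
    """Simulate one patient and run the full analysis chain.

    Returns ``(features, truth, extras)`` where ``extras`` carries the
    intermediate products (activation summary, CCEP graph, significance
    map) for inspection.
    """
    task, truth = generate_task_session(config)
    hg, sig_map, task = analyze_task_session(task, q=q)
    activation = netfeat.summarize_activation(
        sig_map, hg, damping=damping, variance_fraction=variance_fraction
    )
    records = []
    for pair in truth.pairs:
        spes = generate_spes_session(config, pair)
        records.append(
            analyze_spes_session(spes, pair, z_threshold=z_threshold)
        )
    graph = ccep_mod.build_graph(records, z_threshold=z_threshold)
    features = netfeat.assemble_features(
        truth.pairs,
        truth.pair_indices,
        activation,
        truth.esm_labels,
        ccep_graph=graph,
        analyzable=task.good_mask,
    )
    extras = {
        "activation": activation,
        "ccep_graph": graph,
        "significance_map": sig_map,
        "hg": hg,
    }
    return features, truth, extras


def relabel_features(features: pd.DataFrame, truth, config: SynthConfig,
                     coefficients) -> pd.DataFrame:
    """Re-plant ESM labels with new coefficients on existing features."""
    from .synth import plant_esm_labels

    labels = plant_esm_labels(truth, config, coefficients=coefficients)
    out = features.copy()
    out["esm_label"] = [labels[p] for p in out["pair"]]
    return out


def evaluate_patient(
    features: pd.DataFrame,
    model_ids=None,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Cross-validated report per model variant for one patient."""
    model_ids = list(MODEL_FEATURES) if model_ids is None else list(model_ids)
    return {m: fit_cv(features, m, k=k, seed=seed) for m in model_ids}


def evaluate_cohort(
    features_by_patient: dict,
    model_ids=None,
    k: int = 5,
    seed: int = 0,
):
    """Reports, summary table and the model-2 vs model-3 style comparison."""
    reports = {
        pat: evaluate_patient(feats, model_ids, k=k, seed=seed)
        for pat, feats in features_by_patient.items()
    }
    table = summarize_cohort(reports)
    return reports, table
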