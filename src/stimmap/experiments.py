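"""Reusable synthetic-cohort experiments.

These functions define the study conditions for the package's headline
recovery experiments: a cohort of pseudo-patients whose ESM labels are
planted from a connectivity-driven logistic model, analyzed end to end,
and scored per model variant. They are used by the test suite and the
reproduction script alike.
"""

from __future__ import annotations

import numpy as np

from .model import MODEL_FEATURES
from .pipeline import (
    evaluate_patient,
    relabel_features,
    synthetic_patient_features,
)
from .synth import SynthConfig, ground_truth

#: connectivity-coefficient settings of the label-planting scan:
#: none / moderate / strong connectivity dependence
GAMMA3_SETTINGS = (0.0, 1.5, 4.0)

#: the planted coefficients at the "strong connectivity" study condition
STRONG_COEFFICIENTS = (0.0, 0.3, 0.0, 4.0)


def cohort_config(seed: int) -> SynthConfig:
    """One pseudo-patient's study conditions.

    20 channels in two CAR blocks (18 adjacent stimulated pairs,
    matching the 14–18 ESM pairs per patient), 40 task trials, burst
    gain 4× the in-band background, 50 pulses per pair at 2–2.5 s
    jittered intervals.
    """
    return SynthConfig(
        n_channels=20,
        n_blocks=2,
        n_task_trials=40,
        hg_burst_gain=4.0,
        isi_range_s=(2.0, 2.5),
        esm_link_coefficients=STRONG_COEFFICIENTS,
        seed=seed,
    )


def _stratifiable(config: SynthConfig, k: int = 5) -> bool:
    """Both ESM classes populous enough for stratified k-fold CV.

    Mirrors the recorded cohort, where every patient had at least five
    pairs of each class; label counts are checked on the planted truth
    before any signal is generated.
    """
    truth = ground_truth(config)
    labels = np.array(list(truth.esm_labels.values()))
    return labels.sum() >= k and (1 - labels).sum() >= k


def build_cohort(seed: int, n_patients: int = 5, k: int = 5):
    """Simulate and analyze ``n_patients`` usable pseudo-patients.

    Returns a list of ``(features, truth, config)`` triples. Candidate
    seeds are consumed in order; draws whose planted labels could not be
    stratified are skipped.
    """
    out = []
    offset = 0
    while len(out) < n_patients:
        cfg = cohort_config(int(seed) + offset)
        offset += 1
        if offset > 50 * n_patients:
            raise RuntimeError("could not draw a stratifiable cohort")
        if not _stratifiable(cfg, k):
            continue
        features, truth, _ = synthetic_patient_features(cfg)
        out.append((features, truth, cfg))
    return out


def connectivity_gap_experiment(
    seed: int,
    gamma3_values=GAMMA3_SETTINGS,
    n_patients: int = 5,
    k: int = 5,
    model_ids=("eq1", "eq2", "eq3_ccep_z", "eq3_ccep_edges"),
):
    """Mean CV accuracy per model variant vs planted connectivity strength.

    The recordings are simulated once; for each connectivity coefficient
    the ESM labels are re-planted (signals untouched) and every model
    variant re-evaluated with stratified k-fold CV. Returns a dict
    ``{gamma3: {model_id: mean_accuracy_percent}}`` plus the cohort.
    """
    cohort = build_cohort(seed, n_patients=n_patients, k=k)
    results = {}
    for g3 in gamma3_values:
        coeffs = (
            STRONG_COEFFICIENTS[0],
            STRONG_COEFFICIENTS[1],
            STRONG_COEFFICIENTS[2],
            float(g3),
        )
        accs = {m: [] for m in model_ids}
        for features, truth, cfg in cohort:
            feats = relabel_features(features, truth, cfg, coeffs)
            if not _both_classes_stratifiable(feats, k):
                continue
            reports = evaluate_patient(feats, model_ids, k=k, seed=seed)
            for m in model_ids:
                accs[m].append(reports[m].accuracy)
        results[float(g3)] = {
            m: float(np.mean(v)) for m, v in accs.items() if v
        }
    return results, cohort


def _both_classes_stratifiable(features, k: int) -> bool:
    y = features["esm_label"].to_numpy()
    return y.sum() >= k and (1 - y).sum() >= k
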