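import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def tiny_study():
    """Handwritten four-table study: 6 X-ray cases, 6 readers, 2 AI models."""
    cases = pd.DataFrame({
        "case_id": [f"C{i}" for i in range(1, 7)],
        "modality": ["XRAY"] * 6,
        "label": [1, 1, 1, 0, 0, 0],
        "age": [50, 61, 47, 38, 55, 60],
        "sex": ["M", "F", "F", "M", "F", "M"],
    })
    readers = pd.DataFrame({
        "reader_id": [f"R{i}" for i in range(1, 7)],
        "experience_band": ["E0_1", "E0_1", "E1_5", "E5_10", "E10P", "E10P"],
        "breast_specialist": [False] * 6,
        "country": ["RU"] * 6,
    })
    rng = np.random.default_rng(5)
    rows = []
    for r in readers["reader_id"]:
        for c, y in zip(cases["case_id"], cases["label"]):
            base = 4 if y else 2
            rows.append((r, c, int(np.clip(base + rng.integers(-1, 2), 1, 5))))
    ratings = pd.DataFrame(rows, columns=["reader_id", "case_id", "score"])
    scores = pd.DataFrame({
        "model_id": ["M1"] * 6 + ["M2"] * 6,
        "case_id": list(cases["case_id"]) * 2,
        "prob": [0.9, 0.7, 0.8, 0.2, 0.4, 0.1, 0.85, 0.6, 0.9, 0.3, 0.2, 0.15],
    })
    return {"cases": cases, "readers": readers, "ratings": ratings,
            "model_scores": scores}


@pytest.fixture
def binormal_sample():
    """Continuous binormal scores with true AUC 0.85, 200+200 cases."""
    from readerbench.simulate import auc_to_separation

    rng = np.random.default_rng(11)
    d = auc_to_separation(0.85)
    labels = np.concatenate([np.ones(200, int), np.zeros(200, int)])
    scores = labels * d + rng.standard_normal(400)
    return scores, labels
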