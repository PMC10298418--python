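"""Synthetic multi-reader multi-case study generator.

The generator emulates an enriched retrospective reader study: per modality a
fixed case mix (exactly ``round(n_cases * prevalence)`` positive cases — a
fixed-margin design matching an enriched test set, not Bernoulli sampling),
readers in four experience bands who each rate a uniformly random subset of
``set_size`` cases on the 5-point scale, and AI models that score every case
with a probability rounded to 0.01.

The latent model is equal-variance binormal: a rater with class separation
``d`` observes ``z ~ Normal(label * d, 1)``, whose continuous-score AUC is
exactly ``Phi(d / sqrt(2))``.  Readers discretize ``z`` into scores 1..5
through four thresholds placed symmetrically about ``d/2`` with inner
spacing 0.75; because discretization ties cost a little AUC, the reader
separation is calibrated numerically so that the *ordinal ratings
themselves* carry the configured ``reader_auc`` (the closed-form
``d = sqrt(2) * Phi^-1(auc)`` would leave the ratings ~0.01 short).
Independently, with probability ``undefined_rate`` a rating is replaced by
the "undefined" score 3.  AI models score the continuous latent directly and
report ``logistic(alpha * z + beta)`` — a strictly increasing per-model
distortion that leaves the AUC unchanged — rounded to 2 decimals, so their
``d`` uses the closed form.

Case assignment is per reader, ``set_size`` cases each: ``"independent"``
draws each reader's subset independently; ``"balanced"`` deals shuffled
round-robin blocks so per-case response counts are as even as possible
(each reader's set is still a uniformly random subset marginally).

Readers are conditionally independent given the case label; real reader
panels share error modes (difficult cases), so synthetic consensus scores
are, if anything, better behaved than real ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit

from .exceptions import ConfigError
from .io import EXPERIENCE_BANDS

__all__ = [
    "AIModelSpec", "ModalityConfig", "StudyConfig",
    "default_study_config", "load_config", "save_config",
    "simulate_cases", "simulate_readers", "simulate_reader_ratings",
    "simulate_model_scores", "simulate_study",
]

#: inner spacing (in latent SD units) of the four ordinal cut-points
THRESHOLD_SPACING = 0.75


def auc_to_separation(auc: float) -> float:
    """Latent class separation d with Phi(d / sqrt(2)) = auc."""
    return float(np.sqrt(2.0) * stats.norm.ppf(auc))


def _ordinal_auc(d: float) -> float:
    """Closed-form AUC of the 5-category ordinal rating at separation d."""
    cuts = _ordinal_thresholds(d)
    edges = np.concatenate([[-np.inf], cuts, [np.inf]])
    p = np.diff(stats.norm.cdf(edges))          # negative-class category probs
    q = np.diff(stats.norm.cdf(edges - d))      # positive-class category probs
    below = np.concatenate([[0.0], np.cumsum(p)[:-1]])
    return float(np.sum(q * (below + 0.5 * p)))


@lru_cache(maxsize=None)
def ordinal_separation(auc: float) -> float:
    """Separation d at which the ordinal ratings themselves have AUC ``auc``.

    Solves ``_ordinal_auc(d) = auc``; slightly larger than the continuous
    closed form because the 5-point discretization half-weights ties.
    """
    return float(brentq(lambda d: _ordinal_auc(d) - auc, 1e-6, 20.0,
                        xtol=1e-10))


@dataclass
class AIModelSpec:
    """One AI model: its target AUC and the (alpha, beta) score distortion."""
    model_id: str
    auc: float
    alpha: float = 1.0
    beta: float = 0.0


@dataclass
class ModalityConfig:
    """Study composition for one modality.

    Defaults mirror the chest X-ray arm of the study the generator emulates:
    140 cases with 47 positive, reader bands of 36/60/36/53, four AI models.
    """
    modality: str = "XRAY"
    n_cases: int = 140
    prevalence: float = 47.0 / 140.0
    reader_counts: dict = field(default_factory=lambda: {
        "E0_1": 36, "E1_5": 60, "E5_10": 36, "E10P": 53})
    specialist_counts: dict = field(default_factory=dict)
    reader_auc: dict = field(default_factory=lambda: {
        "E0_1": 0.93, "E1_5": 0.94, "E5_10": 0.95, "E10P": 0.97})
    ai_models: list = field(default_factory=lambda: [
        AIModelSpec(f"XRAY-AI{i + 1}", 0.92) for i in range(4)])
    set_size: int = 50
    undefined_rate: float = 0.05
    assignment: str = "independent"

    def validate(self) -> None:
        if self.assignment not in ("independent", "balanced"):
            raise ConfigError(f"unknown assignment scheme {self.assignment!r}")
        if self.modality not in ("XRAY", "FLG", "MMG"):
            raise ConfigError(f"unknown modality {self.modality!r}")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError(f"prevalence {self.prevalence} outside (0, 1)")
        if self.set_size > self.n_cases:
            raise ConfigError(f"set_size {self.set_size} exceeds n_cases "
                              f"{self.n_cases}")
        if not 0.0 <= self.undefined_rate < 1.0:
            raise ConfigError(f"undefined_rate {self.undefined_rate} outside [0, 1)")
        for band, auc in self.reader_auc.items():
            if band not in EXPERIENCE_BANDS:
                raise ConfigError(f"unknown experience band {band!r}")
            if not 0.5 < auc < 1.0:
                raise ConfigError(f"reader AUC {auc} for {band} outside (0.5, 1)")
        for band, count in self.specialist_counts.items():
            if count > self.reader_counts.get(band, 0):
                raise ConfigError(f"more specialists than readers in band {band}")
        for m in self.ai_models:
            if not 0.5 < m.auc < 1.0:
                raise ConfigError(f"AI AUC {m.auc} for {m.model_id} outside (0.5, 1)")
            if m.alpha <= 0:
                raise ConfigError(f"distortion alpha must be > 0 for {m.model_id}")


@dataclass
class StudyConfig:
    """A full synthetic study: one or more modalities and a master seed."""
    modalities: list = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        for mc in self.modalities:
            mc.validate()


# demographic profiles per modality: (age mean, age sd, all-female?)
_DEMOGRAPHICS = {"XRAY": (49, 18, False), "FLG": (53, 19, False),
                 "MMG": (63, 6, True)}


def default_study_config(seed: int = 0) -> StudyConfig:
    """The three-modality composition the generator emulates by default.

    Case mixes 140(47) / 184(84) / 269(167), the published reader-band counts
    (with the mammography specialist subgroup), and 4/2/2 AI models whose
    target AUCs match the reported modality-level AI performance.
    """
    xray = ModalityConfig()
    flg = ModalityConfig(
        modality="FLG", n_cases=184, prevalence=84.0 / 184.0,
        reader_counts={"E0_1": 6, "E1_5": 8, "E5_10": 5, "E10P": 9},
        ai_models=[AIModelSpec(f"FLG-AI{i + 1}", 0.83) for i in range(2)])
    mmg = ModalityConfig(
        modality="MMG", n_cases=269, prevalence=167.0 / 269.0,
        reader_counts={"E0_1": 16, "E1_5": 32, "E5_10": 28, "E10P": 37},
        specialist_counts={"E0_1": 15, "E1_5": 28, "E5_10": 24, "E10P": 29},
        ai_models=[AIModelSpec(f"MMG-AI{i + 1}", 0.89) for i in range(2)])
    return StudyConfig(modalities=[xray, flg, mmg], seed=seed)


def load_config(path) -> StudyConfig:
    """Load a :class:`StudyConfig` from YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    modalities = []
    for mc in raw.get("modalities", []):
        models = [AIModelSpec(**m) for m in mc.pop("ai_models", [])]
        modalities.append(ModalityConfig(ai_models=models, **mc))
    cfg = StudyConfig(modalities=modalities, seed=int(raw.get("seed", 0)))
    cfg.validate()
    return cfg


def save_config(config: StudyConfig, path) -> None:
    """Write a :class:`StudyConfig` as YAML."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def _rng(seed, *key: int) -> np.random.Generator:
    # one stream per (seed, purpose) so outputs are independent of call order
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


_MODALITY_CODE = {"XRAY": 0, "FLG": 1, "MMG": 2}


def simulate_cases(config: ModalityConfig, seed: int = 0) -> pd.DataFrame:
    """Generate the labelled case table for one modality.

    Exactly ``round(n_cases * prevalence)`` cases are positive (fixed-margin
    design); label order, ages and sexes are randomized deterministically
    from ``seed``.
    """
    config.validate()
    rng = _rng(seed, _MODALITY_CODE[config.modality], 0)
    n = config.n_cases
    n_pos = int(round(n * config.prevalence))
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    age_mean, age_sd, all_female = _DEMOGRAPHICS[config.modality]
    ages = np.clip(rng.normal(age_mean, age_sd, n), 18, 95).round().astype(int)
    sexes = np.full(n, "F") if all_female else rng.choice(["M", "F"], n)
    return pd.DataFrame({
        "case_id": [f"{config.modality}-{i + 1:04d}" for i in range(n)],
        "modality": config.modality,
        "label": labels,
        "age": ages,
        "sex": sexes,
    })


def simulate_readers(config: ModalityConfig, seed: int = 0) -> pd.DataFrame:
    """Generate the reader roster for one modality."""
    config.validate()
    rows = []
    for band in EXPERIENCE_BANDS:
        count = config.reader_counts.get(band, 0)
        n_spec = config.specialist_counts.get(band, 0)
        for i in range(count):
            rows.append((f"{config.modality}-{band}-R{i + 1:03d}", band,
                         i < n_spec, "XX"))
    return pd.DataFrame(rows, columns=["reader_id", "experience_band",
                                       "breast_specialist", "country"])


def _ordinal_thresholds(d: float) -> np.ndarray:
    half = THRESHOLD_SPACING / 2.0
    return d / 2.0 + np.array([-3 * half, -half, half, 3 * half])


def _assign_cases(n_cases: int, n_readers: int, set_size: int,
                  scheme: str, rng: np.random.Generator) -> np.ndarray:
    """Case-index subsets per reader under the chosen assignment scheme."""
    if scheme == "independent":
        return np.stack([rng.choice(n_cases, size=set_size, replace=False)
                         for _ in range(n_readers)]) if n_readers else \
            np.empty((0, set_size), dtype=int)
    # balanced: deal consecutive blocks from concatenated shuffles so each
    # case is rated floor/ceil(R*s/n) times
    total = n_readers * set_size
    reps = -(-total // n_cases)
    pool = np.concatenate([rng.permutation(n_cases) for _ in range(reps)])
    blocks = pool[:total].reshape(n_readers, set_size).copy()
    for block in blocks:            # fix rare duplicates at shuffle seams
        seen: set = set()
        for j, c in enumerate(block):
            while c in seen:
                c = int(rng.integers(n_cases))
            seen.add(c)
            block[j] = c
    return blocks


def simulate_reader_ratings(cases: pd.DataFrame, readers: pd.DataFrame,
                            config: ModalityConfig, seed: int = 0) -> pd.DataFrame:
    """Generate per-reader ordinal ratings.

    Each reader is assigned a uniformly random subset of ``set_size`` cases
    (independently per reader, or dealt in balanced round-robin blocks under
    ``assignment="balanced"``); on a case with label ``y`` the reader draws
    ``z ~ Normal(y * d_band, 1)`` with ``d_band`` calibrated so the ordinal
    rating AUC equals ``reader_auc[band]``, and maps ``z`` through the four
    cut-points; independently with probability ``undefined_rate`` the rating
    is replaced by 3.
    """
    config.validate()
    if config.set_size > len(cases):
        raise ConfigError(f"set_size {config.set_size} exceeds the "
                          f"{len(cases)} available cases")
    rng = _rng(seed, _MODALITY_CODE[config.modality], 1)
    case_ids = cases["case_id"].to_numpy()
    labels = cases["label"].to_numpy()
    assignments = _assign_cases(len(cases), len(readers), config.set_size,
                                config.assignment, rng)
    out_reader, out_case, out_score = [], [], []
    for (_, reader), idx in zip(readers.iterrows(), assignments):
        band = reader["experience_band"]
        d = ordinal_separation(config.reader_auc[band])
        cuts = _ordinal_thresholds(d)
        z = labels[idx] * d + rng.standard_normal(config.set_size)
        scores = 1 + np.searchsorted(cuts, z)
        if config.undefined_rate > 0:
            undef = rng.random(config.set_size) < config.undefined_rate
            scores = np.where(undef, 3, scores)
        out_reader.extend([reader["reader_id"]] * config.set_size)
        out_case.extend(case_ids[idx])
        out_score.extend(scores.tolist())
    return pd.DataFrame({"reader_id": out_reader, "case_id": out_case,
                         "score": out_score})


def simulate_model_scores(cases: pd.DataFrame, config: ModalityConfig,
                          seed: int = 0) -> pd.DataFrame:
    """Generate AI model scores: logistic-distorted latents rounded to 0.01.

    Every model scores every case; ``score = logistic(alpha * z + beta)``
    with ``z ~ Normal(label * d, 1)``, ``d = sqrt(2) * Phi^-1(target auc)``.
    """
    config.validate()
    rng = _rng(seed, _MODALITY_CODE[config.modality], 2)
    labels = cases["label"].to_numpy()
    frames = []
    for model in config.ai_models:
        d = auc_to_separation(model.auc)
        z = labels * d + rng.standard_normal(len(cases))
        probs = np.round(expit(model.alpha * z + model.beta), 2)
        frames.append(pd.DataFrame({"model_id": model.model_id,
                                    "case_id": cases["case_id"],
                                    "prob": probs}))
    return pd.concat(frames, ignore_index=True)


def simulate_study(config: StudyConfig) -> dict:
    """Generate a complete study: cases, readers, ratings and model scores.

    Returns a dict of four DataFrames keyed ``cases``, ``readers``,
    ``ratings``, ``model_scores``, concatenated over modalities.  Fully
    reproducible from ``(config, config.seed)``.
    """
    config.validate()
    cases, readers, ratings, scores = [], [], [], []
    for mc in config.modalities:
        c = simulate_cases(mc, config.seed)
        r = simulate_readers(mc, config.seed)
        cases.append(c)
        readers.append(r)
        ratings.append(simulate_reader_ratings(c, r, mc, config.seed))
        scores.append(simulate_model_scores(c, mc, config.seed))
    return {
        "cases": pd.concat(cases, ignore_index=True),
        "readers": pd.concat(readers, ignore_index=True),
        "ratings": pd.concat(ratings, ignore_index=True),
        "model_scores": pd.concat(scores, ignore_index=True),
    }
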