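"""End-to-end reader-vs-AI benchmark: the model/results objects.

:class:`ReaderStudyBenchmark` holds the validated study tables and a
:class:`BenchmarkConfig`; :meth:`ReaderStudyBenchmark.fit` runs, per
modality,

1. AI consensus — midrank calibration of every model, then per-case
   averaging;
2. reader consensus per group (all readers, the four experience bands and,
   for mammography, the breast-imaging-specialist subgroups with the
   minimum-response filter switched off), with the exclusion rules applied;
3. ROC inference on each group's surviving cases intersected with the AI
   consensus cases — empirical AUROC with a DeLong CI, the Youden-optimal
   operating point with Clopper–Pearson CIs, and a paired permutation
   comparison of the group's AUROC against the AI ensemble's on exactly the
   shared cases.

Each report row therefore carries its own paired case count ``n``; the
minimum-response filter binds harder in small groups, so ``n`` legitimately
differs across rows.  The AI row of a modality is evaluated on its cases
shared with the all-readers group (the head-to-head set) when that group
survives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io as data_io
from .consensus import ai_ensemble_consensus, reader_consensus_table
from .exceptions import ConfigError
from .io import EXPERIENCE_BANDS
from .roc import (ComparisonResult, OperatingPoint, RocResult, delong_ci,
                  permutation_test_auc, smooth_roc, youden_operating_point)

logger = logging.getLogger(__name__)

__all__ = ["GroupSpec", "GroupResult", "BenchmarkConfig", "BenchmarkResults",
           "ReaderStudyBenchmark", "run_benchmark", "youden_identity_check"]

READER_GROUPS = ("ALL_READERS",) + EXPERIENCE_BANDS
SPECIALIST_GROUPS = ("SPECIALISTS_ALL", "SPECIALISTS_E0_1", "SPECIALISTS_E1_5",
                     "SPECIALISTS_E5_10", "SPECIALISTS_E10P")


@dataclass(frozen=True)
class GroupSpec:
    """One report row: a modality and a reader group (or the AI ensemble)."""
    modality: str
    group: str
    apply_min_filter: bool = True

    def __post_init__(self):
        if self.group.startswith("SPECIALISTS") and self.modality != "MMG":
            raise ConfigError("specialist groups are defined for MMG only")


@dataclass
class GroupResult:
    spec: GroupSpec
    n: int
    roc: RocResult | None = None
    operating_point: OperatingPoint | None = None
    comparison: ComparisonResult | None = None
    insufficient: bool = False
    note: str = ""


@dataclass
class BenchmarkConfig:
    """Analysis settings.

    level: confidence level for every interval (default 0.95).
    n_permutations: Monte-Carlo permutations per comparison.
    min_responses: minimum ratings per case for non-specialist groups.
    consensus_rule: "upper_median" (default) or "mode_high".
    paired: paired per-case swap permutation scheme (False = unpaired).
    holm: apply a Holm step-down adjustment to the comparison p-values.
    smooth: attach binormal-smoothed curves (display only).
    """
    level: float = 0.95
    n_permutations: int = 10_000
    min_responses: int = 5
    consensus_rule: str = "upper_median"
    paired: bool = True
    holm: bool = False
    smooth: bool = True


def _holm_adjust(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


class ReaderStudyBenchmark:
    """Reader-vs-AI diagnostic accuracy benchmark on one labelled case set.

    Parameters
    ----------
    cases, readers, ratings, model_scores : pandas.DataFrame
        The four study tables in the :mod:`readerbench.io` schemas.
    config : BenchmarkConfig, optional

    Examples
    --------
    >>> from readerbench import simulate, ReaderStudyBenchmark
    >>> study = simulate.simulate_study(simulate.default_study_config(seed=7))
    >>> results = ReaderStudyBenchmark(**study).fit(seed=7)
    >>> print(results.summary())              # doctest: +SKIP
    """

    def __init__(self, cases, readers, ratings, model_scores,
                 config: BenchmarkConfig | None = None):
        self.cases = cases.reset_index(drop=True)
        self.readers = readers.reset_index(drop=True)
        self.ratings = ratings.reset_index(drop=True)
        self.model_scores = model_scores.reset_index(drop=True)
        self.config = config or BenchmarkConfig()
        known = set(self.cases["case_id"])
        stray = set(self.ratings["case_id"]) - known
        if stray:
            raise ConfigError("ratings reference unknown case_ids: "
                              + ", ".join(sorted(stray)[:5]))

    @classmethod
    def from_csv(cls, cases_path, readers_path, ratings_path,
                 model_scores_path, config: BenchmarkConfig | None = None
                 ) -> "ReaderStudyBenchmark":
        """Build the model from the four delimited-text study files."""
        return cls(
            cases=data_io.read_table(cases_path, "cases"),
            readers=data_io.read_table(readers_path, "readers"),
            ratings=data_io.read_table(ratings_path, "ratings"),
            model_scores=data_io.read_table(model_scores_path, "model_scores"),
            config=config,
        )

    # -- group machinery ---------------------------------------------------

    def _group_readers(self, spec: GroupSpec) -> pd.DataFrame:
        readers = self.readers
        if spec.group.startswith("SPECIALISTS"):
            readers = readers[readers["breast_specialist"]]
            band = spec.group.removeprefix("SPECIALISTS_")
            if band != "ALL":
                readers = readers[readers["experience_band"] == band]
        elif spec.group in EXPERIENCE_BANDS:
            readers = readers[readers["experience_band"] == spec.group]
        return readers

    def _consensus_for(self, spec: GroupSpec, ratings_m: pd.DataFrame
                       ) -> pd.DataFrame:
        readers = self._group_readers(spec)
        sub = ratings_m[ratings_m["reader_id"].isin(readers["reader_id"])]
        if sub.empty:
            return pd.DataFrame(columns=["case_id", "value"])
        table = reader_consensus_table(
            sub, min_responses=self.config.min_responses,
            apply_min_filter=spec.apply_min_filter,
            rule=self.config.consensus_rule)
        return table[~table["excluded"]][["case_id", "value"]]

    def _roc_row(self, spec: GroupSpec, merged: pd.DataFrame,
                 compare: bool, seed: int, row_idx: int) -> GroupResult:
        """ROC inference for one group on its paired case set."""
        n = len(merged)
        labels = merged["label"].to_numpy()
        if n == 0 or labels.sum() < 2 or (n - labels.sum()) < 2:
            return GroupResult(spec=spec, n=n, insufficient=True,
                               note="insufficient data")
        values = merged["value"].to_numpy()
        roc = delong_ci(values, labels, level=self.config.level)
        if self.config.smooth:
            try:
                with warnings.catch_warnings():
                    # fallback to the empirical curve is fine for display
                    warnings.simplefilter("ignore", UserWarning)
                    roc.smoothed_curve = smooth_roc(values, labels)
            except Exception:                      # degenerate spread
                roc.smoothed_curve = None
        op = youden_operating_point(values, labels, level=self.config.level)
        comparison = None
        if compare:
            child = int(np.random.SeedSequence([seed, row_idx])
                        .generate_state(1)[0] % 2**31)
            comparison = permutation_test_auc(
                values, merged["ai_value"].to_numpy(), labels,
                n_permutations=self.config.n_permutations, seed=child,
                method="monte_carlo", paired=self.config.paired)
        return GroupResult(spec=spec, n=n, roc=roc, operating_point=op,
                           comparison=comparison)

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int = 0) -> "BenchmarkResults":
        """Run the full benchmark; deterministic given the inputs and seed."""
        rows: list[GroupResult] = []
        row_idx = 0
        for modality in data_io.MODALITIES:
            cases_m = self.cases[self.cases["modality"] == modality]
            if cases_m.empty:
                continue
            case_ids = set(cases_m["case_id"])
            labels_m = cases_m[["case_id", "label"]]
            ratings_m = self.ratings[self.ratings["case_id"].isin(case_ids)]
            scores_m = self.model_scores[
                self.model_scores["case_id"].isin(case_ids)]

            ai_cons = None
            if not scores_m.empty:
                ai_cons = (ai_ensemble_consensus(scores_m)
                           [["case_id", "value"]]
                           .rename(columns={"value": "ai_value"}))
            else:
                logger.warning("modality %s has no AI scores; comparisons "
                               "omitted", modality)

            group_names = list(READER_GROUPS)
            if modality == "MMG" and self.readers["breast_specialist"].any():
                group_names += list(SPECIALIST_GROUPS)

            reader_rows = []
            all_readers_cases = None
            for name in group_names:
                spec = GroupSpec(modality=modality, group=name,
                                 apply_min_filter=not name.startswith("SPECIALISTS"))
                cons = self._consensus_for(spec, ratings_m)
                merged = cons.merge(labels_m, on="case_id")
                if ai_cons is not None:
                    merged = merged.merge(ai_cons, on="case_id")
                row_idx += 1
                result = self._roc_row(spec, merged, ai_cons is not None,
                                       seed, row_idx)
                reader_rows.append(result)
                if name == "ALL_READERS" and not result.insufficient:
                    all_readers_cases = set(merged["case_id"])

            if ai_cons is not None:
                ai_spec = GroupSpec(modality=modality, group="AI",
                                    apply_min_filter=False)
                ai_merged = (ai_cons.rename(columns={"ai_value": "value"})
                             .merge(labels_m, on="case_id"))
                if all_readers_cases is not None:
                    # head-to-head set: AI evaluated on the cases it shares
                    # with the all-readers consensus
                    ai_merged = ai_merged[
                        ai_merged["case_id"].isin(all_readers_cases)]
                row_idx += 1
                rows.append(self._roc_row(ai_spec, ai_merged, False, seed,
                                          row_idx))
            rows.extend(reader_rows)

        if self.config.holm:
            comp_rows = [r for r in rows if r.comparison is not None]
            adjusted = _holm_adjust([r.comparison.p_value for r in comp_rows])
            for r, p in zip(comp_rows, adjusted):
                r.comparison = replace(r.comparison, p_value=p)
        return BenchmarkResults(rows=rows, config=self.config, seed=seed,
                                model=self)


def run_benchmark(cases, readers, ratings, model_scores,
                  config: BenchmarkConfig | None = None,
                  seed: int = 0) -> "BenchmarkResults":
    """Functional one-shot interface over :class:`ReaderStudyBenchmark`."""
    return ReaderStudyBenchmark(cases, readers, ratings, model_scores,
                                config=config).fit(seed=seed)


@dataclass
class BenchmarkResults:
    """Fitted benchmark: one :class:`GroupResult` per (modality, group)."""
    rows: list
    config: BenchmarkConfig
    seed: int
    model: ReaderStudyBenchmark | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Full-precision report table (one row per modality/group)."""
        records = []
        for r in self.rows:
            rec = {"modality": r.spec.modality, "group": r.spec.group,
                   "n": r.n}
            if r.insufficient:
                rec["note"] = r.note
            else:
                rec.update({
                    "auroc": r.roc.auc,
                    "auroc_lo": r.roc.auc_ci[0], "auroc_hi": r.roc.auc_ci[1],
                    "threshold": r.operating_point.threshold,
                    "youden_j": r.operating_point.youden_j,
                    "sens": r.operating_point.sensitivity,
                    "sens_lo": r.operating_point.sensitivity_ci[0],
                    "sens_hi": r.operating_point.sensitivity_ci[1],
                    "spec": r.operating_point.specificity,
                    "spec_lo": r.operating_point.specificity_ci[0],
                    "spec_hi": r.operating_point.specificity_ci[1],
                    "acc": r.operating_point.accuracy,
                    "acc_lo": r.operating_point.accuracy_ci[0],
                    "acc_hi": r.operating_point.accuracy_ci[1],
                    "p_value": (r.comparison.p_value
                                if r.comparison is not None else np.nan),
                    "note": r.note,
                })
            records.append(rec)
        return pd.DataFrame(records)

    def save(self, path) -> None:
        """Write the report as CSV (2-decimal display rounding)."""
        data_io.write_report(self.to_frame(), path)

    def summary(self) -> str:
        """Text report with cells formatted ``x.xx(lo–hi)``."""
        def cell(v, lo, hi):
            return f"{v:.2f}({lo:.2f}–{hi:.2f})"

        lines = ["Reader-vs-AI diagnostic accuracy benchmark",
                 f"confidence level {self.config.level:.0%}, "
                 f"{self.config.n_permutations} permutations "
                 f"({'paired' if self.config.paired else 'unpaired'}), "
                 f"consensus rule {self.config.consensus_rule}, seed {self.seed}",
                 ""]
        header = (f"{'modality':<9}{'group':<18}{'n':>5}  "
                  f"{'AUROC(CI95)':<17}{'Se(CI95)':<17}{'Sp(CI95)':<17}"
                  f"{'Acc(CI95)':<17}{'thr':>6}{'J':>6}  {'p':>7}")
        lines += [header, "-" * len(header)]
        for r in self.rows:
            if r.insufficient:
                lines.append(f"{r.spec.modality:<9}{r.spec.group:<18}"
                             f"{r.n:>5}  {r.note}")
                continue
            op = r.operating_point
            p = (f"{r.comparison.p_value:7.3f}"
                 if r.comparison is not None else "      -")
            lines.append(
                f"{r.spec.modality:<9}{r.spec.group:<18}{r.n:>5}  "
                f"{cell(r.roc.auc, *r.roc.auc_ci):<17}"
                f"{cell(op.sensitivity, *op.sensitivity_ci):<17}"
                f"{cell(op.specificity, *op.specificity_ci):<17}"
                f"{cell(op.accuracy, *op.accuracy_ci):<17}"
                f"{op.threshold:>6.2f}{op.youden_j:>6.2f}  {p}")
        return "\n".join(lines)

    def plot_roc(self, modality: str, ax=None):
        """Plot the smoothed ROC curves of a modality with operating points."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        for r in self.rows:
            if r.spec.modality != modality or r.insufficient:
                continue
            curve = r.roc.smoothed_curve
            if curve is not None:
                ax.plot(curve.fpr, curve.tpr,
                        label=f"{r.spec.group} AUC={r.roc.auc:.2f}")
            op = r.operating_point
            ax.plot(1 - op.specificity, op.sensitivity, "o", color="red",
                    markersize=4)
        ax.plot([0, 1], [0, 1], ":", color="grey", linewidth=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(modality)
        ax.legend(fontsize=7)
        return ax


def youden_identity_check(results: BenchmarkResults) -> pd.DataFrame:
    """Verify J = Se + Sp - 1 for every fitted row, pre-rounding.

    Returns one row per group with the reported J, the value recomputed from
    the operating-point confusion matrix, and a boolean ``ok``.
    """
    records = []
    for r in results.rows:
        if r.insufficient:
            continue
        op = r.operating_point
        recomputed = op.sensitivity + op.specificity - 1.0
        records.append({
            "modality": r.spec.modality, "group": r.spec.group,
            "j_reported": op.youden_j, "j_recomputed": recomputed,
            "ok": bool(np.isclose(op.youden_j, recomputed, rtol=0, atol=1e-12)),
        })
    return pd.DataFrame(records)
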