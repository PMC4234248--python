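"""Correlation of objective quality predictions with MUSHRA rating tables.

The harness mirrors a standard evaluation design: per-subject ratings of
each (condition, talker) stimulus on the 0-100 MUSHRA scale are averaged
over subjects (and optionally over talkers), objective measures are computed
for every stimulus pair, and agreement is quantified by Pearson's r on raw
values and Spearman's rank correlation rs (average ranks on ties), without
any regression mapping of the predictions.

Per-talker correlations pool all (condition, talker) points into a single
correlation; missing cells are dropped pairwise and logged, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .audio import AudioSignal, align_and_scale, read_wav, to_working_rate
from .lpc import LPC_MEASURES, lpc_distance
from .pemo import Audiogram, compute_internal_representation
from .quality import PRESENTATION_LEVEL_DB_SPL, QualityOptions, _bank_for, psm, qc

__all__ = [
    "RATING_COLUMNS",
    "MeasureConfig",
    "EvaluationResult",
    "load_ratings",
    "validate_ratings",
    "aggregate",
    "correlate",
    "run_benchmark",
    "standard_measures",
]

log = logging.getLogger(__name__)

RATING_COLUMNS = ("subject", "group", "condition", "talker", "rating")


@dataclass(frozen=True)
class MeasureConfig:
    """One objective measure to evaluate.

    ``kind`` in {psm, qc, isd, lar, llr, wssd}; PEMO options apply only to
    psm/qc.  ``name`` defaults to the conventional label.
    """

    kind: str
    options: QualityOptions = field(default_factory=QualityOptions)
    name: str | None = None

    def label(self) -> str:
        if self.name:
            return self.name
        if self.kind in ("psm", "qc"):
            return self.options.label(self.kind.upper() if self.kind == "psm" else "qc")
        return self.kind.upper()


def standard_measures(audiogram: Audiogram | None = None) -> list[MeasureConfig]:
    """The 16 PEMO-based variants (8 NH + 8 HI when an audiogram is given,
    else 16 NH/HI collapses to the 8 NH ones) plus the 4 LPC distances.

    PSM variants: lp/fb x +/-B; qc variants: +/-W x +/-B (lp mode).
    """
    out: list[MeasureConfig] = []
    hearing: list[Audiogram | None] = [None]
    if audiogram is not None:
        hearing.append(audiogram)
    for ag in hearing:
        for mode in ("lp", "fb"):
            for assim in (True, False):
                out.append(MeasureConfig("psm", QualityOptions(mode, False, assim, ag)))
        for weight in (True, False):
            for assim in (True, False):
                out.append(MeasureConfig("qc", QualityOptions("lp", weight, assim, ag)))
    out.extend(MeasureConfig(m) for m in LPC_MEASURES)
    return out


# ---------------------------------------------------------------------------
# Ratings

def validate_ratings(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RATING_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ratings table missing columns: {missing}")
    table = table.loc[:, list(RATING_COLUMNS)].copy()
    bad = table.index[(table["rating"] < 0) | (table["rating"] > 100)]
    if len(bad):
        raise ValueError(f"ratings outside [0, 100] at rows {list(bad[:5])}")
    dup = table.duplicated(subset=["subject", "condition", "talker"])
    if dup.any():
        raise ValueError(
            f"duplicate (subject, condition, talker) keys at rows {list(table.index[dup][:5])}"
        )
    return table


def load_ratings(path) -> pd.DataFrame:
    """Load and validate a delimited ratings table (TSV or CSV)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return validate_ratings(pd.read_csv(path, sep=sep))


def aggregate(
    table: pd.DataFrame,
    group: str | None = None,
    average_across_talkers: bool = False,
) -> pd.Series:
    """Mean rating over subjects per (condition, talker), optionally further
    averaged over talkers per condition.

    Returns a Series indexed by (condition, talker) or by condition.
    """
    table = validate_ratings(table)
    if group is not None:
        table = table[table["group"] == group]
        if table.empty:
            raise ValueError(f"no ratings for group {group!r}")
    means = table.groupby(["condition", "talker"], sort=True)["rating"].mean()
    if average_across_talkers:
        means = means.groupby(level="condition").mean()
    return means


def correlate(predictions: pd.Series, means: pd.Series) -> tuple[float, float]:
    """Pearson r and Spearman rs between matched prediction/rating points.

    Keys are matched by index; unmatched keys are dropped pairwise (logged).
    """
    joined = pd.concat(
        [predictions.rename("pred"), means.rename("mos")], axis=1, join="inner"
    ).dropna()
    dropped = max(len(predictions), len(means)) - len(joined)
    if dropped:
        log.warning("correlate: dropped %d unmatched/missing points pairwise", dropped)
    if len(joined) < 3:
        raise ValueError("need >= 3 paired points for a correlation")
    if joined["pred"].nunique() == 1 or joined["mos"].nunique() == 1:
        raise ValueError("degenerate (constant) vector in correlation")
    r = stats.pearsonr(joined["pred"], joined["mos"]).statistic
    rs = stats.spearmanr(joined["pred"], joined["mos"]).statistic
    return float(r), float(rs)


# ---------------------------------------------------------------------------
# Benchmark

@dataclass
class EvaluationResult:
    """Correlation table plus the underlying scatter points.

    ``correlations``: rows (measure, pearson_ind, spearman_ind, pearson_av,
    spearman_av) — "ind." uses per-talker points, "av." talker-averaged ones.
    ``scatter``: long table (measure, condition, talker, prediction, mos).
    """

    correlations: pd.DataFrame
    scatter: pd.DataFrame

    def plot_scatter(self, measure: str, ax=None):
        """Scatter of subjective mean ratings vs. predictions of one measure."""
        import matplotlib.pyplot as plt

        d = self.scatter[self.scatter["measure"] == measure]
        if ax is None:
            _, ax = plt.subplots()
        for cond, sub in d.groupby("condition"):
            ax.plot(sub["prediction"], sub["mos"], "o", label=cond)
        ax.set_xlabel(f"{measure} prediction")
        ax.set_ylabel("mean subjective rating")
        ax.legend(fontsize="x-small")
        return ax


def _pemo_predictions(
    pairs: dict,
    configs: list[MeasureConfig],
) -> dict[str, dict]:
    """Compute all PEMO-based measures, sharing internal representations.

    ``pairs`` maps (condition, talker) -> (test, ref) aligned signals.
    Representations are cached per (talker/ref id, bank, mode, hearing) so
    the +/-W and +/-B variants reuse the same model runs.
    """
    pemo_cfgs = [c for c in configs if c.kind in ("psm", "qc")]
    ir_cache: dict = {}
    out: dict[str, dict] = {c.label(): {} for c in pemo_cfgs}

    def _ir(sig_key, sig, bank_kind, opts: QualityOptions):
        key = (sig_key, bank_kind, opts.modulation_mode, opts.audiogram is not None)
        if key not in ir_cache:
            fb = _bank_for(bank_kind, sig.sample_rate_hz)
            ir_cache[key] = compute_internal_representation(
                sig, fb, opts.audiogram, opts.modulation_mode
            )
        return ir_cache[key]

    for (cond, talker), (test, ref) in pairs.items():
        for cfg in pemo_cfgs:
            o = cfg.options
            ir_t = _ir((cond, talker), test, cfg.kind, o)
            ir_r = _ir(("__ref__", talker), ref, cfg.kind, o)
            score = psm(ir_t, ir_r, o) if cfg.kind == "psm" else qc(ir_t, ir_r, o)
            out[cfg.label()][(cond, talker)] = score.value
    return out


def run_benchmark(
    manifest: pd.DataFrame,
    ratings: pd.DataFrame,
    measures: list[MeasureConfig] | None = None,
    group: str | None = None,
    exclude_anchors: bool = False,
    signals: dict | None = None,
) -> EvaluationResult:
    """Evaluate objective measures against a MUSHRA rating table.

    ``manifest`` has columns (condition, talker, ref_path, test_path); when
    ``signals`` is given it maps (condition, talker) -> (test, ref)
    :class:`AudioSignal` pairs and paths are ignored.  ``exclude_anchors``
    drops the lowpass and clip anchor conditions (the hidden reference and
    anchors are included by default).
    """
    measures = measures if measures is not None else standard_measures()
    ratings = validate_ratings(ratings)

    needed = {(r.condition, r.talker) for r in manifest.itertuples()}
    rated = set(
        ratings.groupby(["condition", "talker"]).groups.keys()
    )
    missing = sorted(rated - needed)
    if missing:
        raise ValueError(f"manifest lacks stimuli for rated cells: {missing}")

    if exclude_anchors:
        manifest = manifest[~manifest["condition"].isin(["lowpass", "clip"])]

    # load + align stimulus pairs
    pairs: dict = {}
    for row in manifest.itertuples():
        key = (row.condition, row.talker)
        if signals is not None:
            test, ref = signals[key]
        else:
            test = to_working_rate(read_wav(row.test_path))
            ref = to_working_rate(read_wav(row.ref_path))
        ref = ref.at_level(PRESENTATION_LEVEL_DB_SPL)
        pairs[key] = align_and_scale(test, ref)

    # crop each talker's pairs to a common length so reference representations
    # can be shared across conditions
    for talker in {t for (_, t) in pairs}:
        keys = [k for k in pairs if k[1] == talker]
        n = min(pairs[k][0].n_samples for k in keys)
        for k in keys:
            test, ref = pairs[k]
            pairs[k] = (
                test.with_samples(test.samples[:n]),
                ref.with_samples(ref.samples[:n]),
            )

    preds: dict[str, dict] = _pemo_predictions(pairs, measures)
    for cfg in measures:
        if cfg.kind in ("psm", "qc"):
            continue
        preds[cfg.label()] = {
            key: lpc_distance(ref, test, cfg.kind) for key, (test, ref) in pairs.items()
        }

    mos_ind = aggregate(ratings, group=group, average_across_talkers=False)
    mos_av = aggregate(ratings, group=group, average_across_talkers=True)

    rows, scat = [], []
    for cfg in measures:
        name = cfg.label()
        p = pd.Series(preds[name])
        p.index = pd.MultiIndex.from_tuples(p.index, names=["condition", "talker"])
        r_i, rs_i = correlate(p, mos_ind)
        p_av = p.groupby(level="condition").mean()
        r_a, rs_a = correlate(p_av, mos_av)
        rows.append(
            {
                "measure": name,
                "pearson_ind": r_i,
                "spearman_ind": rs_i,
                "pearson_av": r_a,
                "spearman_av": rs_a,
            }
        )
        joined = pd.concat([p.rename("prediction"), mos_ind.rename("mos")], axis=1, join="inner")
        for (cond, talker), rr in joined.iterrows():
            scat.append(
                {
                    "measure": name,
                    "condition": cond,
                    "talker": talker,
                    "prediction": rr["prediction"],
                    "mos": rr["mos"],
                }
            )
    return EvaluationResult(pd.DataFrame(rows), pd.DataFrame(scat))
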