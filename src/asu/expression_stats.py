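"""Sense-antisense differential expression statistics.

Covers the expression arm of the pipeline: strand-specific qPCR log2
ratios normalized by a control gene (PDA1 by default), nCounter-style
two-step normalization (positive spike-ins for processing efficiency,
then designed control genes for sample variation), per-target regulation
calls from log2 ratios, counting of discordant sense-antisense pairs
across conditions, and the sense-vs-antisense change correlation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProbeClass",
    "QpcrMeasurement",
    "ExpressionTable",
    "Regulation",
    "RegulationCall",
    "DiscordanceCounts",
    "qpcr_log_ratio",
    "ncounter_normalize",
    "call_regulation",
    "count_discordant_pairs",
    "sense_antisense_correlation",
    "read_expression_table",
    "write_expression_table",
    "read_qpcr_table",
]


class ProbeClass(str, enum.Enum):
    TARGET_SENSE = "target_sense"
    TARGET_ANTISENSE = "target_antisense"
    POSITIVE_SPIKE = "positive_spike"
    CONTROL_GENE = "control_gene"


class Regulation(str, enum.Enum):
    INDUCED = "induced"
    REPRESSED = "repressed"
    NO_CHANGE = "no_change"


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR relative-expression quantity."""

    target_id: str
    orientation: str  # "sense" | "antisense" | "control"
    primer_set: str
    replicate: str
    condition: str
    quantity: float

    def __post_init__(self):
        if self.quantity <= 0:
            raise ValueError("qPCR quantities must be positive")


@dataclass(frozen=True)
class RegulationCall:
    target_id: str
    orientation: str
    condition_pair: str
    log2_ratio: float
    call: Regulation


class ExpressionTable:
    """Probes x samples count matrix with probe classes.

    ``counts`` is a DataFrame indexed by probe id with one column per
    sample; ``probe_class`` maps each probe to a :class:`ProbeClass`.
    At least one positive-spike and one control-gene probe are required
    (they drive normalization).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        probe_class: Mapping[str, ProbeClass],
        sample_info: Optional[pd.DataFrame] = None,
    ):
        counts = counts.astype(float)
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        classes = pd.Series(
            {p: ProbeClass(c) for p, c in dict(probe_class).items()}, name="probe_class"
        )
        missing = set(counts.index) - set(classes.index)
        if missing:
            raise ValueError(f"probes without a class: {sorted(missing)}")
        classes = classes.reindex(counts.index)
        if not (classes == ProbeClass.POSITIVE_SPIKE).any():
            raise ValueError("need at least one positive_spike probe")
        if not (classes == ProbeClass.CONTROL_GENE).any():
            raise ValueError("need at least one control_gene probe")
        self.counts = counts
        self.probe_class = classes
        self.sample_info = sample_info

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def probes_of(self, cls: ProbeClass) -> list[str]:
        return list(self.probe_class.index[self.probe_class == cls])

    def copy_with(self, counts: pd.DataFrame) -> "ExpressionTable":
        return ExpressionTable(counts, self.probe_class.to_dict(), self.sample_info)


def _geometric_mean(values: np.ndarray) -> float:
    if (values <= 0).any():
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(values))))


def ncounter_normalize(
    table: ExpressionTable, ref_sample: Optional[str] = None
) -> ExpressionTable:
    """Two-step normalization against a reference sample (default: first).

    Step 1 scales every sample so its positive-spike sum equals the
    reference's (processing-efficiency control); step 2 further scales
    the mRNA probes (targets and controls, not the spikes) so the
    geometric mean of the control-gene probes equals the reference's
    (sample-amount control). The reference sample is left unchanged
    overall, and the operation is idempotent.
    """
    ref = ref_sample if ref_sample is not None else table.samples[0]
    if ref not in table.counts.columns:
        raise ValueError(f"unknown reference sample {ref!r}")
    spikes = table.probes_of(ProbeClass.POSITIVE_SPIKE)
    controls = table.probes_of(ProbeClass.CONTROL_GENE)

    spike_sums = table.counts.loc[spikes].sum(axis=0)
    if (spike_sums <= 0).any():
        bad = list(spike_sums.index[spike_sums <= 0])
        raise ValueError(f"zero positive-spike sum in sample(s) {bad}")
    step1 = table.counts * (spike_sums[ref] / spike_sums)

    ctrl = step1.loc[controls]
    if (ctrl.values <= 0).any():
        bad = list(ctrl.columns[(ctrl <= 0).any(axis=0)])
        raise ValueError(f"zero control-gene value in sample(s) {bad}")
    geo = ctrl.apply(lambda col: _geometric_mean(col.values), axis=0)
    step2 = step1 * (geo[ref] / geo)
    step2.loc[spikes] = step1.loc[spikes]  # spikes are not mRNA content
    return table.copy_with(step2)


def qpcr_log_ratio(
    meas: Iterable[QpcrMeasurement],
    target: str,
    cond_num: str,
    cond_den: str,
    orientation: Optional[str] = None,
    control_target: str = "PDA1",
) -> tuple[float, float]:
    """Control-normalized qPCR log2 ratio between two conditions.

    Within each (primer_set, replicate) stratum the target quantity is
    divided by the control gene's, and the stratum contributes
    ``log2((T/C)_num / (T/C)_den)``. Returns the mean and the sample
    standard deviation across strata (the error-bar contract: variation
    between biological replicates and different primers pooled). The sd
    is 0.0 with a single stratum.
    """
    meas = list(meas)
    t_rows = [
        m
        for m in meas
        if m.target_id == target
        and (orientation is None or m.orientation == orientation)
        and m.condition in (cond_num, cond_den)
    ]
    if not t_rows:
        raise ValueError(f"no measurements for target {target!r}")
    c_by_stratum: dict[tuple[str, str, str], float] = {}
    for m in meas:
        if m.target_id == control_target and m.condition in (cond_num, cond_den):
            c_by_stratum[(m.primer_set, m.replicate, m.condition)] = m.quantity

    strata = sorted({(m.primer_set, m.replicate) for m in t_rows})
    ratios = []
    for primer_set, replicate in strata:
        vals = {}
        for cond in (cond_num, cond_den):
            t = [
                m.quantity
                for m in t_rows
                if m.primer_set == primer_set
                and m.replicate == replicate
                and m.condition == cond
            ]
            if not t:
                raise ValueError(
                    f"target {target!r} missing in stratum "
                    f"(primer_set={primer_set}, replicate={replicate}, condition={cond})"
                )
            key = (primer_set, replicate, cond)
            if key not in c_by_stratum:
                raise ValueError(
                    f"control {control_target!r} missing in stratum "
                    f"(primer_set={primer_set}, replicate={replicate}, condition={cond})"
                )
            vals[cond] = np.mean(t) / c_by_stratum[key]
        ratios.append(np.log2(vals[cond_num] / vals[cond_den]))
    ratios = np.asarray(ratios)
    sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    return float(np.mean(ratios)), sd


def call_regulation(log2_ratio: float, threshold: float = 1.0) -> Regulation:
    """Induced / repressed / no_change from a log2 ratio (default 2-fold)."""
    if not np.isfinite(log2_ratio):
        raise ValueError("log2 ratio must be finite")
    if log2_ratio >= threshold:
        return Regulation.INDUCED
    if log2_ratio <= -threshold:
        return Regulation.REPRESSED
    return Regulation.NO_CHANGE


@dataclass(frozen=True)
class DiscordanceCounts:
    """Discordant sense-antisense pair counts per condition and overall.

    ``per_condition`` maps condition -> count; ``either`` is the number
    of targets discordant in at least one condition (union), ``both``
    the number discordant in every condition (intersection).
    """

    sense_up_as_down: dict
    sense_down_as_up: dict

    @staticmethod
    def _summary(per_condition_sets: dict) -> dict:
        counts = {c: len(s) for c, s in per_condition_sets.items()}
        sets = list(per_condition_sets.values())
        counts["either"] = len(set().union(*sets)) if sets else 0
        counts["both"] = len(set.intersection(*map(set, sets))) if sets else 0
        return counts


def count_discordant_pairs(calls: Sequence[RegulationCall]) -> DiscordanceCounts:
    """Count sense-induced/antisense-repressed pairs (and the mirror).

    Every target must carry both a sense and an antisense call in each
    condition pair it appears in; unpaired targets raise an error
    listing them.
    """
    by_cond: dict[str, dict[str, dict[str, Regulation]]] = {}
    for c in calls:
        by_cond.setdefault(c.condition_pair, {}).setdefault(c.target_id, {})[
            c.orientation
        ] = c.call

    up_down: dict[str, set] = {}
    down_up: dict[str, set] = {}
    for cond, targets in sorted(by_cond.items()):
        unpaired = sorted(
            t for t, d in targets.items() if {"sense", "antisense"} - set(d)
        )
        if unpaired:
            raise ValueError(f"unpaired targets in {cond!r}: {unpaired}")
        up_down[cond] = {
            t
            for t, d in targets.items()
            if d["sense"] == Regulation.INDUCED and d["antisense"] == Regulation.REPRESSED
        }
        down_up[cond] = {
            t
            for t, d in targets.items()
            if d["sense"] == Regulation.REPRESSED and d["antisense"] == Regulation.INDUCED
        }
    return DiscordanceCounts(
        sense_up_as_down=DiscordanceCounts._summary(up_down),
        sense_down_as_up=DiscordanceCounts._summary(down_up),
    )


def sense_antisense_correlation(
    pairs: Sequence[tuple[float, float]], method: str = "pearson"
) -> float:
    """Correlation between sense and antisense log-ratio changes.

    Pearson by default; ``method="spearman"`` gives the rank
    correlation. A negative value indicates anticorrelated regulation
    of the pair.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (sense, antisense) pairs")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pairs must be finite")
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise ValueError("zero variance in one coordinate")
    if method == "pearson":
        return float(stats.pearsonr(arr[:, 0], arr[:, 1]).statistic)
    if method == "spearman":
        return float(stats.spearmanr(arr[:, 0], arr[:, 1]).statistic)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_table(source) -> ExpressionTable:
    """Read a TSV with probes as rows: a ``probe_class`` column plus one
    column per sample."""
    df = pd.read_csv(source, sep="\t", index_col=0)
    if "probe_class" not in df.columns:
        raise ValueError("expression table needs a 'probe_class' column")
    classes = {p: ProbeClass(c) for p, c in df["probe_class"].items()}
    counts = df.drop(columns=["probe_class"])
    counts.index.name = None
    return ExpressionTable(counts, classes)


def write_expression_table(table: ExpressionTable, dest) -> None:
    out = table.counts.copy()
    out.insert(0, "probe_class", [c.value for c in table.probe_class])
    out.to_csv(dest, sep="\t", index_label="probe")


def read_qpcr_table(source) -> list[QpcrMeasurement]:
    """Read a TSV of (target, orientation, primer_set, replicate,
    condition, quantity)."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"target", "orientation", "primer_set", "replicate", "condition", "quantity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    return [
        QpcrMeasurement(
            row.target, row.orientation, row.primer_set, row.replicate,
            row.condition, float(row.quantity),
        )
        for row in df.itertuples()
    ]
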