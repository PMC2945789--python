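"""Synthetic study generator with planted ground truth.

Generates (a) a yeast-like single-chromosome annotation with planted
antisense units spanning all ORF-coverage tiers and all transcriptional
origin classes, (b) strand-specific paired-end fragment sets with a
configurable strand-flip leak rate, and (c) nCounter-style and qPCR
expression tables with a planted sense-antisense log-fold-change
anticorrelation — so every pipeline stage can be exercised against a
known truth without any external data.

Planted geometry
----------------
Each antisense target locus is built in a '+'-strand frame and mirrored
when the target gene draws the '-' strand. The planted unit's *nominal*
span is the expected fragment-center footprint: fragments are sampled
from the span padded by half a fragment length per side, so the
segmented unit reproduces the nominal span up to sampling jitter
(tens of bp). Tier geometry keeps >= 100 bp away from every tier
threshold and origin geometry keeps >= 50 bp of slack inside/outside
the 400 bp classification margin, so planted labels are unambiguous.

Determinism: every generator is a pure function of (config, seed), and
random streams are partitioned per purpose (placement, fragment
lengths, strand flips, expression noise) so changing one parameter
does not perturb unrelated draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation_io import Annotation, GeneModel, GenomicInterval
from .antisense_catalog import Tier, antisense_fractions, _tier
from .expression_stats import ExpressionTable, ProbeClass, QpcrMeasurement
from .origin_classifier import OriginClass

__all__ = [
    "SimConfig",
    "PlantedUnit",
    "ExpressionPairTruth",
    "SimTruth",
    "simulate_annotation",
    "simulate_fragments",
    "simulate_expression_tables",
]

_TIER_ORDER = (Tier.UTR_ONLY, Tier.GE25, Tier.GE50, Tier.GE75, Tier.FULL)
_ORIGIN_ORDER = (
    OriginClass.SENSE_3UTR_EXTENSION,
    OriginClass.SENSE_5UTR_EXTENSION,
    OriginClass.DIVERGENT_PROMOTER,
    OriginClass.ADJACENT_3NFR,
    OriginClass.UNEXPLAINED,
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    ``depth`` is the mean fragment-center coverage per transcribed base
    (the number of fragments sampled for a transcript is
    ``round(depth * length)``); planted antisense transcripts are
    sequenced at ``antisense_depth_factor`` of that, reflecting the low
    antisense coverage of real libraries. ``leak_rate`` is the per-
    fragment probability of a strand flip (0.62% for a dUTP library).
    """

    # annotation geometry
    n_genes: int = 200
    n_antisense: int = 50
    chrom: str = "chrSim"
    chrom_length: int = 1_000_000
    gene_len_mean: float = 1100.0
    gene_len_sd: float = 250.0
    gene_len_min: int = 600
    gene_len_max: int = 2000
    target_len_min: int = 1200
    target_len_max: int = 1600
    gap_min: int = 1200
    gap_max: int = 1800
    utr_mean: float = 100.0
    utr_sd: float = 20.0
    utr_min: int = 50
    utr_max: int = 200
    tier_mix: dict = field(
        default_factory=lambda: {
            Tier.UTR_ONLY: 0.10,
            Tier.GE25: 0.25,
            Tier.GE50: 0.25,
            Tier.GE75: 0.20,
            Tier.FULL: 0.20,
        }
    )
    origin_mix: dict = field(
        default_factory=lambda: {
            OriginClass.SENSE_3UTR_EXTENSION: 0.12,
            OriginClass.SENSE_5UTR_EXTENSION: 0.07,
            OriginClass.DIVERGENT_PROMOTER: 0.37,
            OriginClass.ADJACENT_3NFR: 0.09,
            OriginClass.UNEXPLAINED: 0.35,
        }
    )
    runthrough_frac: float = 0.3  # of eligible full-ORF units

    # fragment library
    frag_len_mean: float = 250.0
    frag_len_sd: float = 30.0
    frag_len_min: int = 100
    depth: float = 20.0
    antisense_depth_factor: float = 0.1
    leak_rate: float = 0.0062

    # expression arm
    n_expression_pairs: int = 67
    conditions: tuple = ("early_stationary", "heat_shock")
    ref_condition: str = "midlog"
    n_replicates: int = 2
    fc_sd: float = 2.0
    sa_correlation: float = -0.8
    noise_sd: float = 0.3
    sense_baseline: float = 600.0
    baseline_spread: float = 0.5
    antisense_expression_frac: float = 0.1
    n_spikes: int = 6
    n_controls: int = 4
    sample_scale_sd: float = 0.2
    n_qpcr_pairs: int = 6
    qpcr_primer_sd: float = 0.3
    qpcr_stratum_sd: float = 0.4

    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.leak_rate <= 1:
            raise ValueError("leak_rate must be in [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.n_antisense > self.n_genes:
            raise ValueError("n_antisense cannot exceed n_genes")
        for mix in (self.tier_mix, self.origin_mix):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("mix proportions must sum to 1")
        if not -1 <= self.sa_correlation <= 1:
            raise ValueError("sa_correlation must be in [-1, 1]")


@dataclass(frozen=True)
class PlantedUnit:
    unit_id: str
    gene_id: str
    span: GenomicInterval
    tier: Tier
    origin: OriginClass
    runthrough: bool


@dataclass(frozen=True)
class ExpressionPairTruth:
    pair_id: str
    # condition -> (sense log2 fc, antisense log2 fc) vs the reference
    fold_changes: dict


@dataclass
class SimTruth:
    planted_units: list
    expression_pairs: list
    sa_correlation: float

    def to_json(self, dest) -> None:
        payload = {
            "planted_units": [
                {
                    "unit_id": u.unit_id,
                    "gene_id": u.gene_id,
                    "chrom": u.span.chrom,
                    "start": u.span.start,
                    "end": u.span.end,
                    "strand": u.span.strand,
                    "tier": u.tier.value,
                    "origin": u.origin.value,
                    "runthrough": u.runthrough,
                }
                for u in self.planted_units
            ],
            "expression_pairs": [asdict(p) for p in self.expression_pairs],
            "sa_correlation": self.sa_correlation,
        }
        if hasattr(dest, "write"):
            json.dump(payload, dest, indent=1)
        else:
            with open(dest, "w") as fh:
                json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, source) -> "SimTruth":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        units = [
            PlantedUnit(
                d["unit_id"],
                d["gene_id"],
                GenomicInterval(d["chrom"], d["start"], d["end"], d["strand"], d["unit_id"]),
                Tier(d["tier"]),
                OriginClass(d["origin"]),
                d["runthrough"],
            )
            for d in payload["planted_units"]
        ]
        pairs = [
            ExpressionPairTruth(d["pair_id"], {k: tuple(v) for k, v in d["fold_changes"].items()})
            for d in payload["expression_pairs"]
        ]
        return cls(units, pairs, payload["sa_correlation"])


def _apportion(mix: dict, order: Sequence, n: int) -> list:
    """Largest-remainder apportionment of n items to the mix, in order."""
    raw = [(key, n * float(mix.get(key, 0.0))) for key in order]
    counts = {key: int(math.floor(x)) for key, x in raw}
    short = n - sum(counts.values())
    by_remainder = sorted(raw, key=lambda kv: -(kv[1] - math.floor(kv[1])))
    for key, _ in by_remainder[:short]:
        counts[key] += 1
    out = []
    for key in order:
        out.extend([key] * counts[key])
    return out


# ---------------------------------------------------------------------------
# Locus construction (in a '+'-strand frame, mirrored for '-' targets)
# ---------------------------------------------------------------------------

_A_REL = 1100  # ORF start in the locus frame; leaves room for left specials
_SPECIAL_LEN = 500  # ORF length of planted neighbor genes (UTRs 0)


def _target_locus(
    rng: np.random.Generator, config: SimConfig, tier: Tier, origin: OriginClass,
    runthrough: bool,
) -> tuple[list[dict], dict]:
    """Elements of one antisense-target locus in relative '+' coordinates."""
    La = int(rng.integers(config.target_len_min, config.target_len_max + 1))
    a, b = _A_REL, _A_REL + La
    unexplained = origin == OriginClass.UNEXPLAINED

    if tier == Tier.UTR_ONLY:
        utr3 = 1500 if unexplained else 800
        u_start = b + 100
        u_end = b + 950 if unexplained else b + 790
    else:
        utr3 = 100
        u_end = b + 600 if unexplained else b + 150
        if tier == Tier.FULL:
            u_start = a - 150
        elif tier == Tier.GE75:
            u_start = a + round(0.15 * La)
        elif tier == Tier.GE50:
            u_start = a + round(0.375 * La)
        else:  # GE25
            u_start = a + round(0.625 * La)

    elements = [
        {
            "role": "target",
            "start": a,
            "end": b,
            "strand": "+",
            "utr5": 100,
            "utr3": utr3,
        }
    ]
    unit = {"start": u_start, "end": u_end, "strand": "-"}

    # origin-defining neighbor; distances keep >= 50 bp slack inside the
    # 400 bp margin and stay > merge_gap away from the unit's footprint
    if origin == OriginClass.SENSE_3UTR_EXTENSION:
        d = int(rng.integers(250, 351))
        elements.append(
            {"role": "special", "start": u_end + d, "end": u_end + d + _SPECIAL_LEN,
             "strand": "-", "utr5": 0, "utr3": 0}
        )
    elif origin == OriginClass.SENSE_5UTR_EXTENSION:
        d = int(rng.integers(250, 351))
        elements.append(
            {"role": "special", "start": u_start - d - _SPECIAL_LEN, "end": u_start - d,
             "strand": "-", "utr5": 0, "utr3": 0}
        )
    elif origin == OriginClass.DIVERGENT_PROMOTER:
        d = int(rng.integers(100, 351))
        elements.append(
            {"role": "special", "start": u_end + d, "end": u_end + d + _SPECIAL_LEN,
             "strand": "+", "utr5": 0, "utr3": 0}
        )
    # ADJACENT_3NFR relies on the target gene's own 3' UTR end;
    # UNEXPLAINED relies on the clearance built into u_end/u_start.

    if runthrough:
        # convergent '+' gene ending 100 bp from the unit's 3' end
        elements.append(
            {"role": "special", "start": a - 750, "end": a - 250,
             "strand": "+", "utr5": 0, "utr3": 0}
        )

    return elements, unit


def _regular_locus(rng: np.random.Generator, config: SimConfig) -> list[dict]:
    length = int(
        np.clip(
            round(rng.normal(config.gene_len_mean, config.gene_len_sd)),
            config.gene_len_min,
            config.gene_len_max,
        )
    )
    utr5, utr3 = (
        int(np.clip(round(rng.normal(config.utr_mean, config.utr_sd)), config.utr_min, config.utr_max))
        for _ in range(2)
    )
    strand = "+" if rng.random() < 0.5 else "-"
    return [
        {"role": "target", "start": utr5, "end": utr5 + length,
         "strand": strand, "utr5": utr5, "utr3": utr3}
    ]


def _mirror(elements: list[dict], unit: Optional[dict], width: int) -> None:
    """Reflect a locus in place: x -> width - x, strands flipped."""
    flip = {"+": "-", "-": "+"}
    for e in elements:
        e["start"], e["end"] = width - e["end"], width - e["start"]
        e["strand"] = flip[e["strand"]]
    if unit is not None:
        unit["start"], unit["end"] = width - unit["end"], width - unit["start"]
        unit["strand"] = flip[unit["strand"]]


def simulate_annotation(
    config: SimConfig, seed: Optional[int] = None
) -> tuple[Annotation, SimTruth]:
    """Place genes and planted antisense units along one chromosome.

    Same-strand genes never overlap; opposite-strand overlaps occur only
    where an origin-defining neighbor is planted inside a target locus.
    Raises if the chromosome is too short for the requested gene count.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, 0])

    tiers = _apportion(config.tier_mix, _TIER_ORDER, config.n_antisense)
    origins = _apportion(config.origin_mix, _ORIGIN_ORDER, config.n_antisense)
    origins = [origins[i] for i in rng.permutation(len(origins))]
    pairs = list(zip(tiers, origins))
    eligible = [i for i, (t, o) in enumerate(pairs)
                if t == Tier.FULL and o != OriginClass.SENSE_5UTR_EXTENSION]
    n_rt = int(round(config.runthrough_frac * len(eligible)))
    rt_idx = set(
        int(i) for i in rng.permutation(np.array(eligible, dtype=int))[:n_rt]
    ) if eligible else set()

    slots = [("target", i) for i in range(config.n_antisense)]
    slots += [("regular", i) for i in range(config.n_genes - config.n_antisense)]
    slots = [slots[i] for i in rng.permutation(len(slots))]

    genes: dict[str, GeneModel] = {}
    planted: list[PlantedUnit] = []
    cursor = 500
    gene_serial = 0
    for kind, idx in slots:
        if kind == "target":
            tier, origin = pairs[idx]
            elements, unit = _target_locus(rng, config, tier, origin, idx in rt_idx)
        else:
            elements, unit = _regular_locus(rng, config), None
        width = max(e["end"] for e in elements)
        if unit is not None:
            width = max(width, unit["end"])
        if rng.random() < 0.5:
            _mirror(elements, unit, width)

        gene_serial += 1
        base_id = f"g{gene_serial:04d}"
        target_gene_id = None
        n_special = 0
        for e in elements:
            if e["role"] == "target":
                gid = base_id
                target_gene_id = gid
            else:
                n_special += 1
                gid = f"{base_id}n{n_special}"
            genes[gid] = GeneModel(
                gid, config.chrom, e["strand"], cursor + e["start"], cursor + e["end"],
                e["utr5"], e["utr3"],
            )
        if unit is not None:
            uid = f"Planted{len(planted) + 1}"
            planted.append(
                PlantedUnit(
                    uid,
                    target_gene_id,
                    GenomicInterval(
                        config.chrom, cursor + unit["start"], cursor + unit["end"],
                        unit["strand"], uid,
                    ),
                    tier,
                    origin,
                    idx in rt_idx,
                )
            )
        cursor += width + int(rng.integers(config.gap_min, config.gap_max + 1))

    if cursor > config.chrom_length:
        raise ValueError(
            f"chromosome too short: need {cursor} bp for {config.n_genes} genes, "
            f"have {config.chrom_length}"
        )

    annotation = Annotation(genes=genes, chrom_lengths={config.chrom: config.chrom_length})

    # construction self-check: the planted geometry must yield the
    # assigned tier exactly
    for u in planted:
        frac_tx, frac_orf = antisense_fractions(
            u.span, annotation.genes[u.gene_id], config.chrom_length
        )
        if _tier(frac_orf) != u.tier or frac_tx < 0.25:
            raise RuntimeError(
                f"planted geometry for {u.unit_id} yields tier {_tier(frac_orf)} "
                f"(frac_tx={float(frac_tx):.3f}), expected {u.tier}"
            )

    truth = SimTruth(
        planted_units=planted,
        expression_pairs=_plant_expression(config, seed),
        sa_correlation=config.sa_correlation,
    )
    return annotation, truth


def _plant_expression(config: SimConfig, seed: int) -> list[ExpressionPairTruth]:
    rng = np.random.default_rng([seed, 5])
    sigma = config.fc_sd
    cov = sigma**2 * np.array([[1.0, config.sa_correlation], [config.sa_correlation, 1.0]])
    pairs = []
    draws = {
        cond: rng.multivariate_normal([0.0, 0.0], cov, size=config.n_expression_pairs)
        for cond in config.conditions
    }
    for i in range(config.n_expression_pairs):
        fcs = {cond: (float(draws[cond][i, 0]), float(draws[cond][i, 1]))
               for cond in config.conditions}
        pairs.append(ExpressionPairTruth(f"Pair{i + 1}", fcs))
    return pairs


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

def _sample_transcript_fragments(
    rng_len, rng_place, region_start: int, region_end: int, n: int, config: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    region_len = region_end - region_start
    lengths = np.rint(rng_len.normal(config.frag_len_mean, config.frag_len_sd, n))
    lengths = np.maximum(lengths, config.frag_len_min).astype(int)
    for _ in range(100):
        bad = lengths > region_len
        if not bad.any():
            break
        lengths[bad] = np.maximum(
            np.rint(rng_len.normal(config.frag_len_mean, config.frag_len_sd, int(bad.sum()))),
            config.frag_len_min,
        ).astype(int)
    else:
        raise ValueError(
            f"could not sample fragments <= {region_len} bp after 100 attempts"
        )
    starts = region_start + np.floor(
        rng_place.random(n) * (region_len - lengths + 1)
    ).astype(int)
    return starts, lengths


def simulate_fragments(
    annotation: Annotation,
    truth: SimTruth,
    config: SimConfig,
    seed: Optional[int] = None,
) -> list[GenomicInterval]:
    """Strand-specific fragments for every gene and planted antisense unit.

    Each transcript receives exactly ``round(depth * length)`` fragments
    (antisense transcripts scaled by ``antisense_depth_factor``), placed
    uniformly within the transcript span padded by half a fragment
    length per side, and each fragment's strand is flipped independently
    with probability ``leak_rate``.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng_len = np.random.default_rng([seed, 1])
    rng_place = np.random.default_rng([seed, 2])
    rng_flip = np.random.default_rng([seed, 3])
    pad = int(round(config.frag_len_mean / 2))

    transcripts: list[tuple[str, int, int, str, float]] = []
    from .annotation_io import transcript_span

    for gene in sorted(annotation, key=lambda g: g.gene_id):
        span = transcript_span(gene, annotation.chrom_lengths.get(gene.chrom))
        transcripts.append((gene.chrom, span.start, span.end, gene.strand, config.depth))
    for unit in truth.planted_units:
        transcripts.append(
            (unit.span.chrom, unit.span.start, unit.span.end, unit.span.strand,
             config.depth * config.antisense_depth_factor)
        )

    frags: list[GenomicInterval] = []
    flip = {"+": "-", "-": "+"}
    for chrom, start, end, strand, depth in transcripts:
        n = int(round(depth * (end - start)))
        if n <= 0:
            continue
        chrom_len = annotation.chrom_lengths.get(chrom)
        r_start = max(0, start - pad)
        r_end = min(chrom_len, end + pad) if chrom_len else end + pad
        starts, lengths = _sample_transcript_fragments(
            rng_len, rng_place, r_start, r_end, n, config
        )
        flips = rng_flip.random(n) < config.leak_rate
        other = flip[strand]
        frags.extend(
            GenomicInterval(chrom, int(s), int(s + L), other if f else strand)
            for s, L, f in zip(starts, lengths, flips)
        )
    return frags


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def simulate_expression_tables(
    truth: SimTruth, config: SimConfig, seed: Optional[int] = None
) -> tuple[ExpressionTable, list[QpcrMeasurement]]:
    """nCounter-style counts and qPCR quantities for the planted pairs.

    Counts = baseline x 2^(planted log2 fc) x per-sample processing and
    mRNA-amount scales x multiplicative log-normal noise. Positive
    spike-ins see only the processing scale; designed control genes see
    both scales but no fold change, so the two-step normalization can
    undo exactly what was planted. Counts are kept continuous (no
    integer rounding), so the zero-noise limit recovers planted fold
    changes exactly.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng_scale = np.random.default_rng([seed, 6])
    rng_base = np.random.default_rng([seed, 7])
    rng_noise = np.random.default_rng([seed, 8])
    rng_qpcr = np.random.default_rng([seed, 9])

    all_conditions = (config.ref_condition,) + tuple(config.conditions)
    samples = [
        f"{cond}_r{k + 1}" for cond in all_conditions for k in range(config.n_replicates)
    ]
    proc_scale = {
        s: float(np.exp(rng_scale.normal(0.0, config.sample_scale_sd))) for s in samples
    }
    mrna_scale = {
        s: float(np.exp(rng_scale.normal(0.0, config.sample_scale_sd))) for s in samples
    }

    def noisy() -> float:
        if config.noise_sd == 0:
            return 1.0
        return float(2.0 ** rng_noise.normal(0.0, config.noise_sd))

    rows: dict[str, dict[str, float]] = {}
    classes: dict[str, ProbeClass] = {}

    for pair in truth.expression_pairs:
        base_s = config.sense_baseline * float(
            np.exp(rng_base.normal(0.0, config.baseline_spread))
        )
        base_a = base_s * config.antisense_expression_frac
        for suffix, base, cls, col in (
            ("S", base_s, ProbeClass.TARGET_SENSE, 0),
            ("A", base_a, ProbeClass.TARGET_ANTISENSE, 1),
        ):
            probe = f"{pair.pair_id}_{suffix}"
            classes[probe] = cls
            rows[probe] = {}
            for sample in samples:
                cond = sample.rsplit("_r", 1)[0]
                fc = 0.0 if cond == config.ref_condition else pair.fold_changes[cond][col]
                rows[probe][sample] = (
                    base * 2.0**fc * proc_scale[sample] * mrna_scale[sample] * noisy()
                )

    for i in range(config.n_spikes):
        probe = f"Spike{i + 1}"
        classes[probe] = ProbeClass.POSITIVE_SPIKE
        level = 128.0 * 2.0**i
        rows[probe] = {s: level * proc_scale[s] * noisy() for s in samples}

    for i in range(config.n_controls):
        probe = f"Ctrl{i + 1}"
        classes[probe] = ProbeClass.CONTROL_GENE
        level = 800.0 * float(np.exp(rng_base.normal(0.0, 0.3)))
        rows[probe] = {s: level * proc_scale[s] * mrna_scale[s] * noisy() for s in samples}

    counts = pd.DataFrame(rows).T[samples]
    table = ExpressionTable(counts, classes)

    # qPCR arm: two primer sets x two replicates per condition, PDA1 control
    def qpcr_noisy() -> float:
        if config.noise_sd == 0:
            return 1.0
        return float(2.0 ** rng_qpcr.normal(0.0, config.noise_sd))

    qpcr: list[QpcrMeasurement] = []
    qpcr_conditions = (config.ref_condition, config.conditions[0])
    n_q = min(config.n_qpcr_pairs, len(truth.expression_pairs))
    strata = [
        (p, rep, cond)
        for p in ("p1", "p2")
        for rep in ("r1", "r2")
        for cond in qpcr_conditions
    ]
    # the per-reaction scale is shared by every target and the PDA1
    # control of that stratum, so control normalization can cancel it
    stratum_scale = {
        key: float(np.exp(rng_qpcr.normal(0.0, config.qpcr_stratum_sd))) for key in strata
    }
    for p, rep, cond in strata:
        qpcr.append(
            QpcrMeasurement(
                "PDA1", "control", p, rep, cond, stratum_scale[(p, rep, cond)] * qpcr_noisy()
            )
        )
    for pair in truth.expression_pairs[:n_q]:
        primer_offset = {
            (orient, p): float(np.exp(rng_qpcr.normal(0.0, config.qpcr_primer_sd)))
            for orient in ("sense", "antisense")
            for p in ("p1", "p2")
        }
        for p, rep, cond in strata:
            for orient, col in (("sense", 0), ("antisense", 1)):
                fc = 0.0 if cond == config.ref_condition else pair.fold_changes[cond][col]
                qpcr.append(
                    QpcrMeasurement(
                        pair.pair_id, orient, p, rep, cond,
                        2.0**fc
                        * primer_offset[(orient, p)]
                        * stratum_scale[(p, rep, cond)]
                        * qpcr_noisy(),
                    )
                )
    return table, qpcr
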