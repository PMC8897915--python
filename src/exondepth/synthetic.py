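"""Synthetic WES-like coverage with known biases, spiked CNVs, and
truth-based evaluation.

The generator draws a regions x samples Poisson coverage matrix from
lambda = N_j * beta_i * exp(f(gc_i)) * exp((GH)_ij), multiplies carrier
cells by copy_number/2 for each spiked event, and records the ground
truth. The evaluator matches calls to truth one-to-one and stratifies by
carrier frequency (rare <= 1%) and event length (short = 1-2 exons).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .io_coverage import CoverageMatrix, TargetRegion, make_region
from .qc import build_annotations

TRUTH_COLUMNS = [
    "sample_id",
    "chrom",
    "start",
    "end",
    "type",
    "copy_number",
    "n_exons",
    "population_frequency",
]

STRATA = [("all", "rare", "common"), ("all", "short", "long")]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class CnvEvent:
    type: str  # DEL or DUP
    copy_number: int  # 0, 1, 3 or 4
    n_exons: int
    carrier_fraction: float

    def __post_init__(self) -> None:
        if self.type not in ("DEL", "DUP"):
            raise ValueError("event type must be DEL or DUP")
        if self.copy_number not in (0, 1, 3, 4):
            raise ValueError("copy_number must be in {0, 1, 3, 4}")
        if (self.type == "DEL") != (self.copy_number < 2):
            raise ValueError("type and copy_number disagree")
        if self.n_exons < 1:
            raise ValueError("n_exons must be >= 1")
        if not 0 < self.carrier_fraction <= 1:
            raise ValueError("carrier_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SimulationSpec:
    n_regions: int = 200
    n_samples: int = 50
    seed: int = 0
    depth_mean: float = 100.0
    beta_shape: float = 10.0  # gamma shape of region effects (spread of beta)
    libsize_sd: float = 0.2
    gc_bias_strength: float = 2.0
    K_true: int = 0
    factor_scale: float = 0.0
    # 0 = iid gaussian loadings; > 0 = regions fall into loading clusters
    # (capture-batch-like artifacts), each cluster sharing one direction in
    # the K_true-dimensional latent space
    factor_clusters: int = 0
    cnv_events: tuple[CnvEvent, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_regions < 2 or self.n_samples < 1:
            raise ValueError("need >= 2 regions and >= 1 sample")
        if min(self.depth_mean, self.libsize_sd, self.gc_bias_strength,
               self.factor_scale) < 0 or self.K_true < 0:
            raise ValueError("strengths must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        events = tuple(CnvEvent(**e) for e in raw.pop("cnv_events", []))
        return cls(cnv_events=events, **raw)


@dataclass
class SimulationResult:
    matrix: CoverageMatrix
    regions: list[TargetRegion]
    annotations: pd.DataFrame
    truth: pd.DataFrame  # TRUTH_COLUMNS
    lam_true: np.ndarray  # (n, m) CNV-free expectations
    lam_cnv: np.ndarray  # (n, m) expectations including spiked events
    f_gc_true: np.ndarray  # (n,) GC curve evaluated at each region


def _place_events(
    spec: SimulationSpec, rng: np.random.Generator
) -> list[tuple[CnvEvent, int, np.ndarray]]:
    """Draw (event, start_region, carriers) avoiding same-sample overlap."""
    occupied: dict[int, set[int]] = {}
    placed = []
    for event in spec.cnv_events:
        if event.n_exons > spec.n_regions:
            raise SimulationError("event longer than the region set")
        n_carriers = max(1, round(event.carrier_fraction * spec.n_samples))
        for attempt in range(100):
            start = int(rng.integers(0, spec.n_regions - event.n_exons + 1))
            span = range(start, start + event.n_exons)
            carriers = rng.choice(spec.n_samples, size=n_carriers, replace=False)
            conflict = any(
                occupied.get(int(s), set()) & set(span) for s in carriers
            )
            if not conflict:
                break
        else:
            raise SimulationError("could not place CNV events without overlap")
        for s in carriers:
            occupied.setdefault(int(s), set()).update(span)
        placed.append((event, start, np.sort(carriers)))
    return placed


def simulate_coverage(spec: SimulationSpec) -> SimulationResult:
    """Generate coverage, annotations, truth and the true expectations."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_regions, spec.n_samples
    gc = rng.uniform(0.25, 0.75, size=n)
    lengths = rng.integers(100, 501, size=n)
    gaps = rng.integers(500, 2001, size=n)
    starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(lengths)[:-1]])
    regions = [
        make_region("chr1", int(s), int(s + ln)) for s, ln in zip(starts, lengths)
    ]
    n_col = np.exp(rng.normal(0.0, spec.libsize_sd, size=m)) if spec.libsize_sd > 0 else np.ones(m)
    beta = rng.gamma(spec.beta_shape, spec.depth_mean / spec.beta_shape, size=n)
    f_gc = -spec.gc_bias_strength * (gc - 0.5) ** 2
    if spec.K_true > 0 and spec.factor_scale > 0:
        if spec.factor_clusters > 0:
            # contiguous blocks: capture-batch artifacts track genomic position
            cluster = np.arange(n) * spec.factor_clusters // n
            directions = rng.normal(size=(spec.factor_clusters, spec.K_true))
            directions /= np.linalg.norm(directions, axis=1, keepdims=True)
            magnitude = spec.factor_scale * np.abs(rng.normal(1.0, 0.3, size=n))
            g_mat = magnitude[:, None] * directions[cluster]
        else:
            g_mat = rng.normal(0.0, spec.factor_scale, size=(n, spec.K_true))
        h_mat = rng.normal(0.0, 1.0, size=(m, spec.K_true))
        gh = g_mat @ h_mat.T
    else:
        gh = np.zeros((n, m))
    lam_true = n_col[None, :] * beta[:, None] * np.exp(f_gc)[:, None] * np.exp(gh)

    lam_cnv = lam_true.copy()
    truth_rows = []
    sample_ids = [f"S{j:03d}" for j in range(m)]
    for event, start, carriers in _place_events(spec, rng):
        frequency = len(carriers) / m
        span = slice(start, start + event.n_exons)
        for s in carriers:
            lam_cnv[span, s] *= event.copy_number / 2.0
            truth_rows.append(
                {
                    "sample_id": sample_ids[int(s)],
                    "chrom": "chr1",
                    "start": regions[start].start,
                    "end": regions[start + event.n_exons - 1].end,
                    "type": event.type,
                    "copy_number": event.copy_number,
                    "n_exons": event.n_exons,
                    "population_frequency": frequency,
                }
            )
    counts = rng.poisson(lam_cnv)
    matrix = CoverageMatrix(counts, [r.region_id for r in regions], sample_ids)
    annotations = build_annotations(matrix, regions, gc, np.ones(n))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["sample_id", "chrom", "start"]).reset_index(drop=True)
    return SimulationResult(
        matrix=matrix,
        regions=regions,
        annotations=annotations,
        truth=truth,
        lam_true=lam_true,
        lam_cnv=lam_cnv,
        f_gc_true=f_gc,
    )


@dataclass(frozen=True)
class ReadPlacement:
    sample: str
    chrom: str
    start: int
    end: int
    mapq: int = 60
    is_duplicate: bool = False
    is_secondary: bool = False
    is_qcfail: bool = False


def emit_fixture_bams(
    regions: Sequence[TargetRegion],
    placements: Sequence[ReadPlacement],
    out_dir: str | os.PathLike,
) -> dict[str, str]:
    """Write one minimal sorted+indexed BAM per sample from read placements."""
    os.makedirs(out_dir, exist_ok=True)
    contigs: dict[str, int] = {}
    for r in regions:
        contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.end + 1000)
    for p in placements:
        if p.chrom not in contigs:
            raise SimulationError(
                f"placement on undeclared contig {p.chrom!r}"
            )
        if p.end > contigs[p.chrom]:
            contigs[p.chrom] = p.end + 1000
        if p.start < 0 or p.end <= p.start:
            raise SimulationError(f"invalid placement span [{p.start}, {p.end})")
    names = sorted(contigs)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": contigs[name]} for name in names],
    }
    tid = {name: i for i, name in enumerate(names)}
    by_sample: dict[str, list[ReadPlacement]] = {}
    for p in placements:
        by_sample.setdefault(p.sample, []).append(p)
    paths: dict[str, str] = {}
    for sample, reads in by_sample.items():
        path = os.path.join(str(out_dir), f"{sample}.bam")
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            for idx, p in enumerate(
                sorted(reads, key=lambda p: (tid[p.chrom], p.start, p.end))
            ):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = f"read{idx}"
                a.reference_id = tid[p.chrom]
                a.reference_start = p.start
                a.mapping_quality = p.mapq
                length = p.end - p.start
                a.cigartuples = [(0, length)]
                a.query_sequence = "A" * length
                a.query_qualities = pysam.qualitystring_to_array("I" * length)
                a.is_duplicate = p.is_duplicate
                a.is_secondary = p.is_secondary
                a.is_qcfail = p.is_qcfail
                bam.write(a)
        pysam.index(path)
        paths[sample] = path
    return paths


def _call_frequencies(calls: pd.DataFrame, n_samples: int) -> np.ndarray:
    """Cohort frequency per call: fraction of samples with a same-type
    overlapping call (used to stratify FPs, which lack a truth frequency)."""
    freqs = np.zeros(len(calls))
    for i, row in enumerate(calls.itertuples(index=False)):
        mask = (
            (calls["type"] == row.type)
            & (calls["chrom"] == row.chrom)
            & (calls["start"] < row.end)
            & (calls["end"] > row.start)
        )
        freqs[i] = calls.loc[mask, "sample_id"].nunique() / n_samples
    return freqs


def evaluate_calls(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    n_samples: int,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Match calls to truth and tabulate TP/FP/FN per stratum.

    A call is a true positive when a truth event of the same sample and
    type overlaps it by at least one region; each truth event matches at
    most one call (greedy by overlap size, ties leftmost). Truth-side
    strata come from the truth event; FP strata use the call's own exon
    count and its cohort frequency among calls.
    """
    calls = calls.reset_index(drop=True)
    truth = truth.reset_index(drop=True)
    if sample_ids is not None:
        cohort = set(sample_ids)
        unknown = set(calls["sample_id"]) - cohort
        if unknown:
            raise SimulationError(
                f"call sample(s) {sorted(unknown)} absent from truth cohort"
            )
    pairs = []
    for t in truth.itertuples():
        for c in calls.itertuples():
            if (
                c.sample_id == t.sample_id
                and c.type == t.type
                and c.chrom == t.chrom
                and c.start < t.end
                and c.end > t.start
            ):
                overlap = min(c.end, t.end) - max(c.start, t.start)
                pairs.append((overlap, c.start, t.Index, c.Index))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2], p[3]))
    matched_truth: set[int] = set()
    matched_call: set[int] = set()
    for overlap, _, t_idx, c_idx in pairs:
        if t_idx in matched_truth or c_idx in matched_call:
            continue
        matched_truth.add(t_idx)
        matched_call.add(c_idx)

    def freq_stratum(freq: float) -> str:
        return "rare" if freq <= 0.01 else "common"

    def len_stratum(n_exons: int) -> str:
        return "short" if n_exons <= 2 else "long"

    call_freqs = _call_frequencies(calls, n_samples)
    rows = []
    for fs in STRATA[0]:
        for ls in STRATA[1]:
            tp = fp = fn = 0
            for t in truth.itertuples():
                t_fs = freq_stratum(t.population_frequency)
                t_ls = len_stratum(t.n_exons)
                if fs not in ("all", t_fs) or ls not in ("all", t_ls):
                    continue
                if t.Index in matched_truth:
                    tp += 1
                else:
                    fn += 1
            for c in calls.itertuples():
                if c.Index in matched_call:
                    continue
                c_fs = freq_stratum(call_freqs[c.Index])
                c_ls = len_stratum(c.n_exons)
                if fs in ("all", c_fs) and ls in ("all", c_ls):
                    fp += 1
            precision = tp / (tp + fp) if tp + fp else 0.0
            sensitivity = tp / (tp + fn) if tp + fn else 0.0
            rows.append(
                {
                    "frequency": fs,
                    "length": ls,
                    "tp": tp,
                    "fp": fp,
                    "fn": fn,
                    "precision": precision,
                    "sensitivity": sensitivity,
                }
            )
    return pd.DataFrame(rows)


def write_truth_tsv(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_truth_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise SimulationError(f"{path}: missing truth column(s) {missing}")
    return df


def write_targets_bed(regions: Sequence[TargetRegion], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
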