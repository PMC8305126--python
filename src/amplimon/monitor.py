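"""Longitudinal variant tracking and benchmark harness.

Per-patient serial plasma samples are assembled into a timeline; each
variant's frequency trajectory is tabulated across timepoints (0 when a
QC-passing sample lacks the variant, missing when the sample failed QC),
and variants first appearing after baseline that are absent from both the
matched tumor and the baseline plasma are flagged as new.

The benchmark harness simulates the spike-in dilution series plus a
healthy-donor cohort, runs the complete pipeline on every sample, and
reports per-level detection, specificity and the agreement between
theoretical and measured variant frequencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import PanelDefinition
from .readfilter import FilterConfig
from .simulate import (
    DEFAULT_DILUTION_COPIES,
    DEFAULT_READS_PER_SAMPLE,
    DEFAULT_WT_COPIES,
    ErrorModel,
    default_spike_variant,
    make_dilution_series,
    make_healthy_cohort,
)
from .varcall import CallerConfig, SampleResult, VariantKey, process_sample


def variant_label(key: VariantKey) -> str:
    return "|".join(map(str, key))


@dataclass
class Timepoint:
    label: str
    ordinal: float
    result: SampleResult


@dataclass
class PatientTimeline:
    """Ordered serial samples for one patient, with tumor/baseline sets."""

    patient_id: str
    tumor_variants: frozenset[VariantKey]
    timepoints: list[Timepoint]
    baseline_variants: frozenset[VariantKey] = frozenset()

    def trajectory(self) -> pd.DataFrame:
        """Variant x timepoint frequency table.

        A variant absent from a QC-passing timepoint is 0.0; entries from
        QC-failing timepoints are NaN (missing, not zero).
        """
        keys = sorted(
            {v.key for tp in self.timepoints for v in tp.result.positive_calls}
        )
        data = {}
        for tp in self.timepoints:
            if tp.result.qc_pass:
                freqs = {v.key: v.frequency for v in tp.result.positive_calls}
                col = [freqs.get(k, 0.0) for k in keys]
            else:
                freqs = {v.key: v.frequency for v in tp.result.positive_calls}
                col = [freqs.get(k, np.nan) for k in keys]
            data[tp.label] = col
        return pd.DataFrame(
            data, index=[variant_label(k) for k in keys], dtype=float
        )


def build_timeline(
    patient_id: str,
    tumor_variants,
    timepoints: list[tuple[str, float, SampleResult]],
) -> PatientTimeline:
    """Assemble a timeline; the earliest timepoint is the baseline."""
    if not timepoints:
        raise ValueError("need at least one timepoint")
    labels = [lbl for lbl, _, _ in timepoints]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate timepoint labels in {labels}")
    ordered = sorted(timepoints, key=lambda x: x[1])
    tps = [Timepoint(lbl, ordn, res) for lbl, ordn, res in ordered]
    baseline = tps[0]
    baseline_keys = (
        frozenset(v.key for v in baseline.result.positive_calls)
        if baseline.result.qc_pass
        else frozenset()
    )
    return PatientTimeline(
        patient_id=patient_id,
        tumor_variants=frozenset(tumor_variants),
        timepoints=tps,
        baseline_variants=baseline_keys,
    )


@dataclass(frozen=True)
class NewVariantFlag:
    key: VariantKey
    first_label: str
    frequency: float


def flag_new_variants(timeline: PatientTimeline) -> list[NewVariantFlag]:
    """Variants first appearing after baseline, absent from tumor and
    baseline plasma; monotone in the tumor set (adding a tumor variant can
    only remove flags)."""
    known = set(timeline.tumor_variants) | set(timeline.baseline_variants)
    flags: dict[VariantKey, NewVariantFlag] = {}
    for tp in timeline.timepoints[1:]:
        for call in tp.result.positive_calls:
            if call.key in known or call.key in flags:
                continue
            flags[call.key] = NewVariantFlag(call.key, tp.label, call.frequency)
    return sorted(flags.values(), key=lambda f: f.key)


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    """Dilution-series detection plus healthy-cohort specificity."""

    dilution: pd.DataFrame  # one row per (level, replicate)
    specificity: float
    n_healthy: int
    healthy_positive_counts: list[int]
    variant: VariantKey | None = None

    def detection_table(self) -> pd.DataFrame:
        g = self.dilution[self.dilution["level_copies"] > 0].groupby(
            "level_copies", as_index=False
        )
        return g.agg(
            theoretical_vaf=("theoretical_vaf", "first"),
            replicates=("detected", "size"),
            detected=("detected", "sum"),
            mean_measured_vaf=("measured_vaf", "mean"),
        )

    def lowest_full_detection_vaf(self) -> float | None:
        """Smallest theoretical VAF detected in every replicate, or None."""
        t = self.detection_table()
        full = t[t["detected"] == t["replicates"]]
        if full.empty:
            return None
        return float(full["theoretical_vaf"].min())

    def correlation(self, min_theoretical: float = 0.0) -> float:
        """Pearson r between theoretical and measured VAF over detected
        replicates at levels with theoretical VAF >= ``min_theoretical``."""
        d = self.dilution
        sel = d[(d["detected"]) & (d["theoretical_vaf"] >= min_theoretical)]
        if len(sel) < 2 or sel["theoretical_vaf"].nunique() < 2:
            return float("nan")
        return float(
            np.corrcoef(sel["theoretical_vaf"], sel["measured_vaf"])[0, 1]
        )


def run_dilution_benchmark(
    panel: PanelDefinition,
    copies: tuple[float, ...] = DEFAULT_DILUTION_COPIES,
    wt_copies: int = DEFAULT_WT_COPIES,
    replicates: int = 3,
    reads_per_sample: int = DEFAULT_READS_PER_SAMPLE,
    n_healthy: int = 12,
    healthy_reads: int = DEFAULT_READS_PER_SAMPLE,
    error: ErrorModel | None = None,
    caller_config: CallerConfig | None = None,
    filter_config: FilterConfig | None = None,
    seed: int = 0,
    variant: VariantKey | None = None,
) -> BenchmarkResult:
    """Full spike-in benchmark: sensitivity and specificity in one run.

    Dilution samples are simulated on the spiked target's single-amplicon
    sub-panel (the spike-in characterizes the assay at the known SNP
    locus, so the whole read budget is informative); the spiked variant is
    supplied as tumor-confirmed, mirroring a spike-in whose identity is
    known a priori.  Healthy samples run on the full panel with an empty
    tumor set; specificity is the fraction with zero positive calls.
    """
    variant = variant or default_spike_variant(panel)
    spike_panel = panel.subset([variant[0]])
    samples, manifest = make_dilution_series(
        spike_panel,
        copies=copies,
        wt_copies=wt_copies,
        replicates=replicates,
        reads_per_sample=reads_per_sample,
        error=error,
        seed=seed,
        variant=variant,
    )
    tumor_set = frozenset([variant])
    rows = []
    for s, (_, m) in zip(samples, manifest.iterrows()):
        res = process_sample(
            s, spike_panel, filter_config, caller_config,
            tumor_variants=tumor_set, sample_id=s.sample_id,
        )
        hit = next((v for v in res.positive_calls if v.key == variant), None)
        rows.append(
            {
                "sample_id": s.sample_id,
                "level_copies": m["level_copies"],
                "replicate": m["replicate"],
                "theoretical_vaf": m["theoretical_vaf"],
                "detected": hit is not None,
                "measured_vaf": hit.frequency if hit else np.nan,
                "alt_count": hit.alt_count if hit else 0,
                "dedup_depth": hit.depth if hit else res.read_counts.get(variant[0], 0),
            }
        )
    dilution = pd.DataFrame(rows)

    healthy = (
        make_healthy_cohort(
            panel, n_samples=n_healthy, reads_per_sample=healthy_reads,
            wt_copies=wt_copies, error=error, seed=seed,
        )
        if n_healthy > 0
        else []
    )
    positive_counts = []
    for s in healthy:
        res = process_sample(
            s, panel, filter_config, caller_config, sample_id=s.sample_id
        )
        positive_counts.append(len(res.positive_calls))
    specificity = (
        sum(1 for c in positive_counts if c == 0) / n_healthy if n_healthy else 1.0
    )
    return BenchmarkResult(
        dilution=dilution,
        specificity=specificity,
        n_healthy=n_healthy,
        healthy_positive_counts=positive_counts,
        variant=variant,
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def render_report(obj, outdir=None) -> dict[str, str]:
    """Deterministic machine- and human-readable report files.

    Returns {filename: content}; writes the files when ``outdir`` is given.
    """
    files: dict[str, str] = {}
    if isinstance(obj, PatientTimeline):
        traj = obj.trajectory()
        files["trajectory.tsv"] = traj.to_csv(sep="\t", index_label="variant")
        flags = flag_new_variants(obj)
        lines = ["variant\tfirst_appearance\tfrequency"]
        lines += [
            f"{variant_label(f.key)}\t{f.first_label}\t{f.frequency:.6f}"
            for f in flags
        ]
        files["new_variants.tsv"] = "\n".join(lines) + "\n"
        summary = {
            "patient_id": obj.patient_id,
            "n_timepoints": len(obj.timepoints),
            "timepoints": [
                {
                    "label": tp.label,
                    "ordinal": tp.ordinal,
                    "qc_pass": tp.result.qc_pass,
                    "n_positive": len(tp.result.positive_calls),
                }
                for tp in obj.timepoints
            ],
            "tumor_variants": sorted(map(variant_label, obj.tumor_variants)),
            "baseline_variants": sorted(map(variant_label, obj.baseline_variants)),
            "new_variants": [
                {
                    "variant": variant_label(f.key),
                    "first_appearance": f.first_label,
                    "frequency": f.frequency,
                }
                for f in flags
            ],
        }
        files["summary.json"] = json.dumps(summary, indent=2) + "\n"
    elif isinstance(obj, BenchmarkResult):
        files["dilution.tsv"] = obj.dilution.to_csv(sep="\t", index=False)
        files["detection.tsv"] = obj.detection_table().to_csv(sep="\t", index=False)
        summary = {
            "specificity": obj.specificity,
            "n_healthy": obj.n_healthy,
            "healthy_positive_counts": obj.healthy_positive_counts,
            "variant": variant_label(obj.variant) if obj.variant else None,
            "lowest_full_detection_vaf": obj.lowest_full_detection_vaf(),
            "pearson_r_detected": obj.correlation(),
        }
        files["summary.json"] = json.dumps(summary, indent=2) + "\n"
    else:
        raise TypeError(f"cannot render report for {type(obj).__name__}")
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, content in files.items():
            (outdir / name).write_text(content)
    return files
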