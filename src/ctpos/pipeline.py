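"""End-to-end runs: simulate/load -> segment -> measure -> test -> report.

A positioning run takes a cohort of multi-channel stacks (either simulated
from a :class:`~ctpos.synthetic_data.CohortSpec` or read from TIFF files),
segments the nucleus and every paint channel, measures each territory's
%RD, shell and volume, calls per-nucleus ploidy, and writes a report
bundle of CSV tables (per-territory measurements, shell distributions,
median/IQR, volumes, ploidy cohort table) plus a log carrying the package
version, seed and a config hash.  Runs are fully deterministic under a
fixed seed: two runs of the same config produce byte-identical CSVs.

An expression run ingests one or two gene tables plus a chromosome
annotation and emits the deregulation profile, overlap summary and the
deregulation-vs-gene-density r².

Diploid and aneuploid nuclei are kept as separate strata and additionally
pooled, so both views are always available to the statistics.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .expression import (
    ChromosomeAnnotation,
    GeneRecord,
    density_correlation,
    filter_deregulated,
    gene_ids,
    overlap,
    percent_deregulation,
)
from .geometry import ShellIndex, lamina_distance, radial_distance, shell_of
from .imaging_io import DEFAULT_VOXEL_SIZE_UM, StackSet, read_stack
from .population_stats import (
    PloidyCall,
    ShellDistribution,
    call_ploidy,
    compare_shell_distributions,
    kruskal_wallis,
    ks_two_sample,
    median_iqr,
    ploidy_cohort_summary,
)
from .segmentation import (
    DEFAULT_MIN_VOXELS,
    label_objects,
    nucleus_object,
    threshold_channel,
)
from .synthetic_data import CohortSpec, simulate_cohort

__all__ = [
    "PipelineError",
    "PositioningConfig",
    "PositioningReport",
    "run_positioning",
    "compare_shell_tables",
    "volumes_by_shell_test",
    "ExpressionConfig",
    "run_expression",
]


class PipelineError(RuntimeError):
    """A stage failure, tagged with stage name and cell id."""


@dataclass
class PositioningConfig:
    """One condition's positioning run.

    Exactly one of ``cohort`` (simulation spec) or ``stack_paths`` must be
    set.  Channel roles default to the synthetic generator's naming:
    nucleus ``"dapi"``, every other non-lamina/non-locus channel a
    territory paint.
    """

    condition: str
    cohort: CohortSpec | None = None
    stack_paths: list[str] = field(default_factory=list)
    nucleus_channel: str = "dapi"
    territory_channels: list[str] | None = None
    lamina_channel: str | None = None
    locus_channel: str | None = None
    threshold_method: object = "otsu"
    min_voxels_territory: int = DEFAULT_MIN_VOXELS
    min_voxels_locus: int = 10
    default_voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    seed: int = 0
    out_dir: str | None = None

    def config_hash(self) -> str:
        def default(o):
            return asdict(o) if hasattr(o, "__dataclass_fields__") else str(o)

        payload = asdict(self)
        payload.pop("out_dir", None)  # where results land is not part of the analysis
        blob = json.dumps(payload, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PositioningReport:
    condition: str
    measurements: pd.DataFrame
    nuclei: pd.DataFrame
    shell_distributions: pd.DataFrame
    median_iqr_table: pd.DataFrame
    volume_table: pd.DataFrame
    ploidy_calls: list[PloidyCall]
    ploidy_summary: dict
    loci: pd.DataFrame | None = None

    def shell_distribution(self, chromosome: str, stratum: str = "pooled") -> ShellDistribution:
        sub = self.measurements
        sub = sub[sub["chromosome"] == chromosome]
        if stratum != "pooled":
            sub = sub[sub["stratum"] == stratum]
        return ShellDistribution.from_rd_percent(
            f"{self.condition}/{chromosome}/{stratum}", sub["rd_percent"].to_numpy()
        )


def _iter_cells(config: PositioningConfig):
    if (config.cohort is None) == (not config.stack_paths):
        raise PipelineError(
            "[config] exactly one of cohort or stack_paths must be provided"
        )
    if config.cohort is not None:
        for cell_id, stack, _truth in simulate_cohort(config.cohort):
            yield cell_id, stack
    else:
        for path in config.stack_paths:
            yield Path(path).stem, read_stack(path, config.default_voxel_size_um)


def _measure_cell(config: PositioningConfig, cell_id: str, stack: StackSet):
    vox = stack.voxel_size
    try:
        nuc_img = stack[config.nucleus_channel]
        nuc_mask = threshold_channel(nuc_img, config.threshold_method)
        nucleus = nucleus_object(nuc_mask, vox, nuc_img.intensities)
    except Exception as exc:
        raise PipelineError(f"[segment-nucleus] {cell_id}: {exc}") from exc
    filled = np.zeros(stack.shape, dtype=bool)
    filled[tuple(nucleus.voxel_indices.T)] = True

    territory_channels = config.territory_channels
    if territory_channels is None:
        skip = {config.nucleus_channel, config.lamina_channel, config.locus_channel}
        territory_channels = [c for c in stack.names if c not in skip]

    rows, calls = [], []
    for chrom in territory_channels:
        try:
            img = stack[chrom]
            mask = threshold_channel(img, config.threshold_method)
            objects = label_objects(
                mask, config.min_voxels_territory, vox, img.intensities, chrom
            )
        except Exception as exc:
            raise PipelineError(f"[segment-territory {chrom}] {cell_id}: {exc}") from exc
        calls.append(call_ploidy(cell_id, chrom, objects))
        for obj in objects:
            try:
                rm = radial_distance(filled, nucleus.centroid_um, obj.centroid_um, vox)
            except Exception as exc:
                raise PipelineError(f"[radial-distance {chrom}] {cell_id}: {exc}") from exc
            rows.append(
                {
                    "cell_id": cell_id,
                    "chromosome": chrom,
                    "copy_label": obj.label,
                    "copy_count": len(objects),
                    "X_um": rm.X_um,
                    "Y_um": rm.Y_um,
                    "rd_percent": rm.rd_percent,
                    "shell": shell_of(rm.rd_percent).name,
                    "volume_um3": obj.volume_um3,
                }
            )

    locus_rows = []
    if config.locus_channel and config.locus_channel in stack:
        anchor_name = config.lamina_channel or config.nucleus_channel
        try:
            anchor_img = stack[anchor_name]
            anchor_mask = threshold_channel(anchor_img, config.threshold_method)
            locus_img = stack[config.locus_channel]
            locus_mask = threshold_channel(locus_img, config.threshold_method)
            spots = label_objects(
                locus_mask, config.min_voxels_locus, vox, locus_img.intensities,
                config.locus_channel,
            )
            for spot in spots:
                lm = lamina_distance(spot.center_of_mass_um, anchor_mask, vox, anchor_name)
                locus_rows.append(
                    {
                        "cell_id": cell_id,
                        "spot_label": spot.label,
                        "distance_um": lm.distance_um,
                        "anchor": anchor_name,
                    }
                )
        except Exception as exc:
            raise PipelineError(f"[locus] {cell_id}: {exc}") from exc

    nucleus_row = {
        "cell_id": cell_id,
        "volume_um3": nucleus.volume_um3,
        "centroid_z_um": nucleus.centroid_um[0],
        "centroid_y_um": nucleus.centroid_um[1],
        "centroid_x_um": nucleus.centroid_um[2],
    }
    return rows, nucleus_row, calls, locus_rows


def run_positioning(config: PositioningConfig) -> PositioningReport:
    """Run one condition end to end; optionally write the report bundle."""
    all_rows, nuclei_rows, calls, locus_rows = [], [], [], []
    n_cells = 0
    for cell_id, stack in _iter_cells(config):
        n_cells += 1
        rows, nucleus_row, cell_calls, cell_loci = _measure_cell(config, cell_id, stack)
        all_rows.extend(rows)
        nuclei_rows.append(nucleus_row)
        calls.extend(cell_calls)
        locus_rows.extend(cell_loci)
    if n_cells == 0:
        raise PipelineError("[input] empty input set: no cells to measure")

    measurements = pd.DataFrame(all_rows)
    if not measurements.empty:
        measurements["stratum"] = np.where(
            measurements["copy_count"] == 2,
            "diploid",
            np.where(measurements["copy_count"] > 2, "aneuploid", "loss"),
        )

    shell_rows, mi_rows, vol_rows = [], [], []
    if not measurements.empty:
        strata = ["pooled", "diploid", "aneuploid"]
        for chrom, group in measurements.groupby("chromosome"):
            for stratum in strata:
                sub = group if stratum == "pooled" else group[group["stratum"] == stratum]
                if sub.empty:
                    continue
                dist = ShellDistribution.from_rd_percent(
                    f"{config.condition}/{chrom}/{stratum}", sub["rd_percent"].to_numpy()
                )
                shell_rows.append(
                    {
                        "chromosome": chrom,
                        "stratum": stratum,
                        **{f"shell_{s.name}": dist.counts[s] for s in ShellIndex},
                        "n": dist.n,
                    }
                )
                med, iqr = median_iqr(sub["rd_percent"])
                mi_rows.append(
                    {
                        "chromosome": chrom,
                        "stratum": stratum,
                        "n": len(sub),
                        "median_rd": med,
                        "iqr_rd": iqr,
                    }
                )
                vmed, viqr = median_iqr(sub["volume_um3"])
                vol_rows.append(
                    {
                        "chromosome": chrom,
                        "stratum": stratum,
                        "n": len(sub),
                        "median_volume_um3": vmed,
                        "iqr_volume_um3": viqr,
                    }
                )

    report = PositioningReport(
        condition=config.condition,
        measurements=measurements,
        nuclei=pd.DataFrame(nuclei_rows),
        shell_distributions=pd.DataFrame(shell_rows),
        median_iqr_table=pd.DataFrame(mi_rows),
        volume_table=pd.DataFrame(vol_rows),
        ploidy_calls=calls,
        ploidy_summary=ploidy_cohort_summary(calls),
        loci=pd.DataFrame(locus_rows) if locus_rows else None,
    )
    if config.out_dir:
        _write_positioning(config, report)
    return report


def _write_positioning(config: PositioningConfig, report: PositioningReport) -> None:
    out = Path(config.out_dir) / config.condition
    out.mkdir(parents=True, exist_ok=True)
    fmt = {"float_format": "%.6g", "index": False}
    report.measurements.to_csv(out / "measurements.csv", **fmt)
    report.nuclei.to_csv(out / "nuclei.csv", **fmt)
    report.shell_distributions.to_csv(out / "shell_distributions.csv", **fmt)
    report.median_iqr_table.to_csv(out / "median_iqr.csv", **fmt)
    report.volume_table.to_csv(out / "volumes.csv", **fmt)
    ploidy_df = pd.DataFrame(
        [
            {"chromosome": chrom, **row}
            for chrom, row in sorted(report.ploidy_summary.items())
        ]
    )
    ploidy_df.to_csv(out / "ploidy.csv", **fmt)
    if report.loci is not None:
        report.loci.to_csv(out / "loci.csv", **fmt)
    with open(out / "run.log", "w") as fh:
        fh.write(f"ctpos {__version__}\n")
        fh.write(f"condition: {config.condition}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"config_hash: {config.config_hash()}\n")
        fh.write(f"threshold_method: {config.threshold_method}\n")
        fh.write(f"min_voxels_territory: {config.min_voxels_territory}\n")


def compare_shell_tables(
    a: PositioningReport, b: PositioningReport, stratum: str = "pooled"
) -> pd.DataFrame:
    """Per-chromosome shell-distribution tests between two conditions."""
    rows = []
    chroms = sorted(
        set(a.measurements.get("chromosome", pd.Series(dtype=str)))
        & set(b.measurements.get("chromosome", pd.Series(dtype=str)))
    )
    for chrom in chroms:
        da = a.shell_distribution(chrom, stratum)
        db = b.shell_distribution(chrom, stratum)
        if da.n == 0 or db.n == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmp = compare_shell_distributions(da, db)
        rows.append(
            {
                "chromosome": chrom,
                "stratum": stratum,
                "n_a": da.n,
                "n_b": db.n,
                "chi2_statistic": cmp.chi2_statistic,
                "chi2_p": cmp.chi2_p,
                "min_fisher_p": min(cmp.fisher_p_per_shell.values()),
                "tests_disagree": cmp.tests_disagree,
            }
        )
    return pd.DataFrame(rows)


def volumes_by_shell_test(
    report: PositioningReport, chromosome: str, stratum: str = "aneuploid"
) -> tuple[float, float]:
    """Kruskal–Wallis on territory volumes grouped by sub-shell."""
    sub = report.measurements
    sub = sub[(sub["chromosome"] == chromosome)]
    if stratum != "pooled":
        sub = sub[sub["stratum"] == stratum]
    groups = [g["volume_um3"].to_numpy() for _, g in sub.groupby("shell") if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need territories in >= 2 shells")
    return kruskal_wallis(groups)


def compare_locus_distances(a: PositioningReport, b: PositioningReport) -> dict:
    """KS comparison of raw locus-to-lamina distance distributions."""
    if a.loci is None or b.loci is None:
        raise ValueError("both reports need locus measurements")
    d, p = ks_two_sample(a.loci["distance_um"], b.loci["distance_um"])
    return {
        "D": d,
        "p": p,
        "median_a_um": float(a.loci["distance_um"].median()),
        "median_b_um": float(b.loci["distance_um"].median()),
    }


# --------------------------------------------------------------------------
# expression runs


@dataclass
class ExpressionConfig:
    """Expression-side run: one or two conditions against one annotation."""

    conditions: dict[str, object]  # name -> path or list[GeneRecord]
    annotation: object  # path or list[ChromosomeAnnotation]
    fc_cutoff: float = 2.0
    p_cutoff: float = 0.05
    out_dir: str | None = None


def _load_records(source) -> list[GeneRecord]:
    if isinstance(source, (str, Path)):
        from .imaging_io import read_gene_table

        return read_gene_table(source)
    return list(source)


def _load_annotation(source) -> list[ChromosomeAnnotation]:
    if isinstance(source, (str, Path)):
        from .imaging_io import read_annotation

        return read_annotation(source)
    return list(source)


def run_expression(config: ExpressionConfig) -> dict:
    """Deregulation profiles, pairwise overlap and density r² per condition."""
    annotation = _load_annotation(config.annotation)
    results: dict = {"cutoffs": {"fc": config.fc_cutoff, "p": config.p_cutoff}}
    dereg_sets: dict[str, set[str]] = {}
    profiles = {}
    for name, source in config.conditions.items():
        records = _load_records(source)
        up, down = filter_deregulated(records, config.fc_cutoff, config.p_cutoff)
        dereg = up + down
        try:
            profile = percent_deregulation(dereg, annotation, condition=name)
        except KeyError as exc:
            raise PipelineError(f"[expression {name}] {exc}") from exc
        profiles[name] = profile
        dereg_sets[name] = gene_ids(dereg)
        results[name] = {
            "n_up": len(up),
            "n_down": len(down),
            "n_deregulated": len(dereg),
            "percent_dereg": dict(profile.percent_dereg),
            "significant_chromosomes": profile.significant_chromosomes,
            "density_r2": density_correlation(profile, annotation),
        }
    names = list(config.conditions)
    if len(names) == 2:
        ua, ub, common = overlap(dereg_sets[names[0]], dereg_sets[names[1]])
        results["overlap"] = {
            "unique_to_" + names[0]: ua,
            "unique_to_" + names[1]: ub,
            "common": common,
        }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, profile in profiles.items():
            pd.DataFrame(
                {
                    "chromosome": list(profile.percent_dereg),
                    "n_deregulated": [profile.n_deregulated[c] for c in profile.percent_dereg],
                    "percent_dereg": [profile.percent_dereg[c] for c in profile.percent_dereg],
                    "significant": [profile.significant[c] for c in profile.percent_dereg],
                }
            ).to_csv(out / f"deregulation_{name}.csv", index=False, float_format="%.6g")
        with open(out / "expression_summary.json", "w") as fh:
            json.dump(results, fh, indent=2, default=str)
    return results
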