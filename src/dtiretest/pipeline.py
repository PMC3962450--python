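"""End-to-end two-stream test-retest study orchestration.

`run_study` simulates a cohort, randomly assigns each subject's two
back-to-back scans to two independent analysis streams (so acquisition order
cannot influence the results), fits tensors per stream, extracts region
means under per-stream FA templates, and produces the reliability tables,
Bland-Altman agreement outputs, and voxelwise ICC maps, all reproducibly
from two integer seeds.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import default_scheme, write_bvals_bvecs
from .phantom import (
    PhantomConfig,
    default_regions,
    generate_cohort,
)
from .reliability import (
    bland_altman,
    PairedSeries,
    reliability_summary,
    reliability_table,
    voxelwise_icc,
)
from .roi import build_measurement_table
from .tensor import METRICS, fit_volume

__all__ = [
    "ConfigError",
    "StudyConfig",
    "SubjectMeta",
    "assign_streams",
    "disease_burden",
    "make_subject_metadata",
    "run_study",
    "StudyResult",
    "STAGES",
]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "roi", "reliability", "voxelwise")


class ConfigError(ValueError):
    """Invalid or unparsable study configuration."""


@dataclass(frozen=True)
class StudyConfig:
    """Flat study configuration; every field is a documented config-file key."""

    n_control: int = 12
    n_hd: int = 10
    grid_shape: tuple = (20, 20, 10)
    between_subject_cv: float = 0.10
    within_subject_cv: float = 0.02
    rician_sigma: float = 1.0
    s0: float = 100.0
    hd_md_scale: float = 1.10
    hd_fa_flatten: float = 0.10
    n_directions: int = 42
    n_b0: int = 7
    bvalue: float = 1000.0
    fa_threshold: float = 0.2
    seed: int = 0
    stream_assignment_seed: int = 1
    n_controls_without_t1: int = 0
    output_dir: str = "study_out"
    save_images: bool = False

    def phantom_config(self) -> PhantomConfig:
        return PhantomConfig(
            grid_shape=tuple(self.grid_shape),
            regions=default_regions(),
            n_control=self.n_control,
            n_hd=self.n_hd,
            between_subject_cv=self.between_subject_cv,
            within_subject_cv=self.within_subject_cv,
            rician_sigma=self.rician_sigma,
            s0=self.s0,
            seed=self.seed,
            hd_md_scale=self.hd_md_scale,
            hd_fa_flatten=self.hd_fa_flatten,
        )


_FIELD_TYPES = {f.name: f for f in fields(StudyConfig)}


def _coerce(key: str, raw: str):
    if key not in _FIELD_TYPES:
        raise ConfigError(f"unknown config key {key!r}")
    default = getattr(StudyConfig(), key)
    if isinstance(default, bool):
        if raw.lower() in ("1", "true", "yes"):
            return True
        if raw.lower() in ("0", "false", "no"):
            return False
        raise ConfigError(f"{key}: expected a boolean, got {raw!r}")
    if isinstance(default, int):
        try:
            return int(raw)
        except ValueError as exc:
            raise ConfigError(f"{key}: expected an integer, got {raw!r}") from exc
    if isinstance(default, float):
        try:
            return float(raw)
        except ValueError as exc:
            raise ConfigError(f"{key}: expected a number, got {raw!r}") from exc
    if isinstance(default, tuple):
        try:
            return tuple(int(p) for p in raw.replace(",", " ").split())
        except ValueError as exc:
            raise ConfigError(f"{key}: expected integers, got {raw!r}") from exc
    return raw


def load_config(path=None, overrides: dict | None = None) -> StudyConfig:
    """Read a flat ``key = value`` config file, then apply overrides."""
    values: dict = {}
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (part.strip() for part in line.split("=", 1))
            values[key] = _coerce(key, raw)
    for key, raw in (overrides or {}).items():
        values[key] = _coerce(key, raw) if isinstance(raw, str) else raw
    try:
        return StudyConfig(**values)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


@dataclass(frozen=True)
class SubjectMeta:
    """Cohort metadata: demographics and disease markers for one subject."""

    subject_id: str
    group: str
    age: float
    cag: int | None = None
    tfc: int | None = None

    def __post_init__(self) -> None:
        if (self.cag is not None) != (self.group == "hd"):
            raise ValueError("cag must be present iff group is 'hd'")


def disease_burden(age: float, cag: float) -> float:
    """Cumulative pathology index age × (CAG − 35.5)."""
    return age * (cag - 35.5)


def make_subject_metadata(config: StudyConfig) -> pd.DataFrame:
    """Simulated demographics table for the cohort.

    Controls: age ~ N(45.9, 15.7²) within [23, 68], TFC 13.  Patients:
    age ~ N(51.0, 7.7²) within [42, 67], CAG ~ round N(43.3, 2.4²) within
    [39, 46], TFC ~ round N(11.5, 1.3²) within [9, 13]; disease burden is
    age × (CAG − 35.5).
    """
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 9999])
    rows = []
    for i in range(config.n_control):
        age = float(np.clip(rng.normal(45.9, 15.7), 23.0, 68.0))
        rows.append(
            {
                "subject_id": f"control_{i+1:02d}",
                "group": "control",
                "age": round(age, 2),
                "cag": np.nan,
                "tfc": 13,
                "disease_burden": np.nan,
            }
        )
    for i in range(config.n_hd):
        age = round(float(np.clip(rng.normal(51.0, 7.7), 42.0, 67.0)), 2)
        cag = int(np.clip(round(rng.normal(43.3, 2.4)), 39, 46))
        tfc = int(np.clip(round(rng.normal(11.5, 1.3)), 9, 13))
        rows.append(
            {
                "subject_id": f"hd_{i+1:02d}",
                "group": "hd",
                "age": age,
                "cag": cag,
                "tfc": tfc,
                "disease_burden": round(disease_burden(age, cag), 2),
            }
        )
    return pd.DataFrame(rows)


def assign_streams(scans, seed: int) -> dict:
    """Randomly assign each subject's two scans to streams A and B.

    ``scans`` maps subject id → a sequence of exactly two scan identifiers
    (an iterable of subject ids means scans ``(1, 2)``).  A seeded fair coin
    per subject (in sorted subject order) decides which scan goes to stream
    A; each stream receives exactly one scan per subject.
    """
    if not hasattr(scans, "items"):
        scans = {sid: (1, 2) for sid in scans}
    rng = np.random.default_rng(seed)
    assignment = {}
    for sid in sorted(scans):
        pair = tuple(scans[sid])
        if len(pair) != 2:
            raise ValueError(f"subject {sid} has {len(pair)} scans, expected 2")
        flip = rng.integers(0, 2)
        a, b = (pair[1], pair[0]) if flip else pair
        assignment[sid] = {"A": a, "B": b}
    return assignment


@dataclass
class StudyResult:
    """Everything `run_study` computed, plus where it was written."""

    config: StudyConfig
    cohort: object = None
    streams: dict = field(default_factory=dict)
    measurements: pd.DataFrame = None
    reliability: pd.DataFrame = None
    summary: pd.DataFrame = None
    bland_altman_summary: pd.DataFrame = None
    voxelwise_maps: dict = field(default_factory=dict)
    manifest: pd.DataFrame = None
    output_files: list = field(default_factory=list)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def _save_nifti(data: np.ndarray, affine: np.ndarray, path: Path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), path)


def run_study(config: StudyConfig, stage: str = "all") -> StudyResult:
    """Run the study through ``stage`` (one of STAGES, or "all").

    Writes TSV tables, NIfTI volumes and a run manifest under
    ``config.output_dir``; idempotent and reproducible for fixed seeds.
    """
    if stage == "all":
        stage = STAGES[-1]
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}, expected one of {STAGES}")
    last = STAGES.index(stage)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = StudyResult(config=config)
    manifest_rows: list = []
    timings: dict = {}

    def record(name: str, value) -> None:
        manifest_rows.append({"key": name, "value": str(value)})

    def stage_done(name: str, t0: float) -> None:
        timings[name] = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs", name, timings[name])

    # --- simulate -----------------------------------------------------------
    t0 = time.perf_counter()
    scheme = default_scheme(config.n_directions, config.n_b0, config.bvalue)
    pcfg = config.phantom_config()
    cohort = generate_cohort(pcfg, scheme)
    metadata = make_subject_metadata(config)
    result.cohort = cohort
    write_bvals_bvecs(scheme, out / "bvals", out / "bvecs")
    _save_nifti(cohort.labels, cohort.affine, out / "labels.nii.gz")
    pd.DataFrame(
        sorted(cohort.region_names.items()), columns=["label_id", "region_name"]
    ).to_csv(out / "labels.tsv", sep="\t", index=False)
    _write_tsv(cohort.truth_manifest(), out / "truth.tsv")
    _write_tsv(metadata, out / "participants.tsv")
    if config.save_images:
        cohort.to_directory(out / "dwi")
    stage_done("simulate", t0)
    if last < 1:
        return _finalize(result, out, manifest_rows, timings, record)

    # --- fit (stream assignment + per-stream tensor fits) -------------------
    t0 = time.perf_counter()
    subject_ids = [s.subject_id for s in cohort.subjects]
    streams = assign_streams(subject_ids, config.stream_assignment_seed)
    result.streams = streams
    stream_df = pd.DataFrame(
        [
            {"subject_id": sid, "stream_A_scan": v["A"], "stream_B_scan": v["B"]}
            for sid, v in sorted(streams.items())
        ]
    )
    _write_tsv(stream_df, out / "stream_assignment.tsv")

    mask = cohort.labels > 0
    maps: dict = {}
    n_nonconverged = 0
    for subj in cohort.subjects:
        for stream_idx, stream_name in ((1, "A"), (2, "B")):
            repeat = streams[subj.subject_id][stream_name]
            vf = fit_volume(subj.dwi[repeat - 1], scheme, mask=mask)
            n_nonconverged += vf.n_nonconverged
            maps[(subj.subject_id, stream_idx)] = {
                m: vf.maps[m] for m in METRICS
            }
    record("n_nonconverged_voxels", n_nonconverged)
    stage_done("fit", t0)
    if last < 2:
        return _finalize(result, out, manifest_rows, timings, record)

    # --- roi (per-stream FA templates, measurement table) --------------------
    t0 = time.perf_counter()
    fa_templates = {
        stream_idx: np.mean(
            [maps[(sid, stream_idx)]["FA"].data for sid in subject_ids], axis=0
        )
        for stream_idx in (1, 2)
    }
    groups = {s.subject_id: s.group for s in cohort.subjects}
    regions = [(r.label_id, r.region_name, r.atlas) for r in pcfg.regions]
    atlas_regions = [r for r in regions if r[2]]
    t1_regions = [r for r in regions if not r[2]]

    tables = []
    if atlas_regions:
        tables.append(
            build_measurement_table(
                maps, cohort.labels, atlas_regions, groups,
                fa_templates=fa_templates, fa_threshold=config.fa_threshold,
            )
        )
    if t1_regions:
        # reduced-sample path: the first n_controls_without_t1 controls have
        # no T1 segmentation and drop out of the T1-ROI analysis
        no_t1 = {f"control_{i+1:02d}" for i in range(config.n_controls_without_t1)}
        t1_maps = {key: m for key, m in maps.items() if key[0] not in no_t1}
        tables.append(
            build_measurement_table(
                t1_maps, cohort.labels, t1_regions, groups,
                fa_templates=fa_templates, fa_threshold=config.fa_threshold,
            )
        )
    measurements = (
        pd.concat(tables, ignore_index=True)
        .sort_values(["subject_id", "repeat", "region", "metric"], kind="stable")
        .reset_index(drop=True)
    )
    result.measurements = measurements
    _write_tsv(measurements, out / "measurements.tsv")
    stage_done("roi", t0)
    if last < 3:
        return _finalize(result, out, manifest_rows, timings, record)

    # --- reliability (per-group ICC tables, pooled Bland-Altman) -------------
    t0 = time.perf_counter()
    rel = reliability_table(measurements)
    summ = reliability_summary(rel)
    result.reliability = rel
    result.summary = summ
    _write_tsv(rel, out / "reliability.tsv")
    _write_tsv(summ, out / "reliability_summary.tsv")

    ba_rows = []
    ba_pairs = []
    t1_names = {name for _, name, _ in t1_regions}
    ba_source = measurements[measurements["region"].isin(t1_names)] if t1_names else measurements
    for (region, metric), cell in ba_source.groupby(["region", "metric"], sort=True):
        wide = cell.pivot(index="subject_id", columns="repeat", values="value")
        series = PairedSeries(wide[[1, 2]].to_numpy(), tuple(wide.index))
        ba = bland_altman(series)
        ba_rows.append(
            {
                "region": region,
                "metric": metric,
                "n": series.n,
                "mean_diff": ba.mean_diff,
                "sd_diff": ba.sd_diff,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
            }
        )
        pairs = ba.pairs.copy()
        pairs.insert(0, "metric", metric)
        pairs.insert(0, "region", region)
        ba_pairs.append(pairs)
    ba_summary = pd.DataFrame(ba_rows)
    result.bland_altman_summary = ba_summary
    _write_tsv(ba_summary, out / "bland_altman.tsv")
    _write_tsv(pd.concat(ba_pairs, ignore_index=True), out / "bland_altman_pairs.tsv")
    stage_done("reliability", t0)
    if last < 4:
        return _finalize(result, out, manifest_rows, timings, record)

    # --- voxelwise ICC maps ---------------------------------------------------
    t0 = time.perf_counter()
    for group in ("control", "hd"):
        sids = [s.subject_id for s in cohort.subjects if s.group == group]
        if len(sids) < 2:
            continue
        for metric in METRICS:
            stack1 = np.stack([maps[(sid, 1)][metric].data for sid in sids])
            stack2 = np.stack([maps[(sid, 2)][metric].data for sid in sids])
            icc_map, n_undef = voxelwise_icc(
                stack1, stack2, mask=mask, subject_ids1=sids, subject_ids2=sids
            )
            name = f"voxelwise_icc_{metric}_{group}.nii.gz"
            _save_nifti(icc_map, cohort.affine, out / name)
            result.voxelwise_maps[(metric, group)] = icc_map
            record(f"n_undefined_voxels_{metric}_{group}", n_undef)
    stage_done("voxelwise", t0)
    return _finalize(result, out, manifest_rows, timings, record)


def _finalize(result, out: Path, manifest_rows, timings, record) -> StudyResult:
    import nibabel
    import scipy

    config = result.config
    for key, value in config.__dict__.items():
        record(f"config.{key}", value)
    for lib in (np, scipy, pd, nibabel):
        record(f"version.{lib.__name__}", lib.__version__)
    for name, seconds in timings.items():
        record(f"wall_time_s.{name}", f"{seconds:.3f}")
    files = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.tsv"
    )
    for name in files:
        record(f"output_file.{name}", name)
    manifest = pd.DataFrame(manifest_rows, columns=["key", "value"])
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    result.manifest = manifest
    result.output_files = [out / f for f in files] + [out / "manifest.tsv"]
    missing = [str(p) for p in result.output_files if not p.exists() or p.stat().st_size == 0]
    if missing:
        raise RuntimeError(f"missing or empty outputs: {missing}")
    return result
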