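"""Dataset I/O, pipeline orchestration, reporting, and the CLI.

File formats: NIfTI-1 volumes (images float32, masks uint8) with the echo
times of a multi-echo stack in a JSON sidecar (DICOM ``EchoTime`` is
honoured when reading DICOM series); CSV tables (UTF-8, '.' decimal) at
full float precision; a markdown report with display rounding and
Bland-Altman plots. Every pipeline stage writes a ``provenance.json`` with
the hash of the run configuration so that artefacts from different runs
cannot be mixed in a report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import click
import matplotlib
import nibabel as nib
import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import mti, relaxometry, reliability, synthetic
from .errors import ConfigError, DesignError
from .synthetic import (AcquisitionGeometry, CohortTruth, Grid, MTPair,
                        MultiEchoStack, RoiMask)

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

logger = logging.getLogger("qmrn.io_report")


# --------------------------------------------------------------------------
# Checksums and NIfTI helpers
# --------------------------------------------------------------------------


def sha256_file(path: Path | str) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _affine(grid: Grid) -> np.ndarray:
    pr, pc = grid.pixel_mm
    return np.diag([pr, pc, grid.slice_thickness_mm, 1.0])


def _grid_from_nifti(img: nib.Nifti1Image) -> Grid:
    rows, cols, n_slices = img.shape[:3]
    zooms = img.header.get_zooms()[:3]
    fov = rows * float(zooms[0])
    return Grid(rows=rows, cols=cols, n_slices=n_slices,
                slice_thickness_mm=float(zooms[2]), fov_mm=fov)


def save_volume(path: Path | str, data: np.ndarray, grid: Grid) -> None:
    """Write a (slice, row, col) volume as (row, col, slice) NIfTI-1."""
    vol = np.transpose(np.asarray(data, dtype=np.float32), (1, 2, 0))
    nib.save(nib.Nifti1Image(vol, _affine(grid)), str(path))


def load_volume(path: Path | str) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    grid = _grid_from_nifti(img)
    data = np.transpose(np.asarray(img.dataobj, dtype=np.float32), (2, 0, 1))
    return data, grid


def save_mask(path: Path | str, mask: RoiMask) -> None:
    vol = np.transpose(mask.data.astype(np.uint8), (1, 2, 0))
    nib.save(nib.Nifti1Image(vol, _affine(mask.grid)), str(path))


def load_mask(path: Path | str, label: str = "") -> RoiMask:
    img = nib.load(str(path))
    grid = _grid_from_nifti(img)
    data = np.transpose(np.asarray(img.dataobj) > 0, (2, 0, 1))
    return RoiMask(data, grid, label or Path(path).stem)


def save_mse_stack(path: Path | str, stack: MultiEchoStack) -> None:
    """Write a multi-echo stack as 4-D NIfTI plus a TE JSON sidecar."""
    vol = np.transpose(stack.data, (2, 3, 0, 1))  # (row, col, slice, echo)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), _affine(stack.grid)),
             str(path))
    Path(path).with_suffix(".json").write_text(
        json.dumps({"EchoTime_ms": list(stack.te_ms)}))


def load_mse_stack(path: Path | str) -> MultiEchoStack:
    img = nib.load(str(path))
    sidecar = Path(path).with_suffix(".json")
    if not sidecar.exists():
        raise ConfigError(
            f"missing TE sidecar {sidecar}; a multi-echo stack needs its "
            "echo times (EchoTime_ms)")
    te = json.loads(sidecar.read_text())["EchoTime_ms"]
    grid = _grid_from_nifti(img)
    data = np.transpose(np.asarray(img.dataobj, dtype=np.float32),
                        (2, 3, 0, 1))
    return MultiEchoStack(data, tuple(te), grid)


def echo_times_from_dicom(paths) -> list[float]:
    """Echo times [ms] from a DICOM series, sorted ascending."""
    import pydicom

    tes = sorted({float(pydicom.dcmread(str(p),
                                        stop_before_pixels=True).EchoTime)
                  for p in paths})
    if not tes:
        raise ConfigError("no EchoTime tags found in the DICOM series")
    return tes


# --------------------------------------------------------------------------
# Manifest
# --------------------------------------------------------------------------


class Manifest:
    """Index of one on-disk dataset (subject, scan, reader, role, path)."""

    REQUIRED = ("subject", "scan", "reader", "role", "path", "checksum")

    def __init__(self, frame: pd.DataFrame, root: Path):
        missing = set(self.REQUIRED) - set(frame.columns)
        if missing:
            raise ConfigError(f"manifest missing columns {missing}")
        self.frame = frame
        self.root = Path(root)

    @classmethod
    def load(cls, path: Path | str, verify: bool = True) -> "Manifest":
        path = Path(path)
        frame = pd.read_csv(path, keep_default_na=False)
        m = cls(frame, path.parent)
        for _, row in frame.iterrows():
            fp = m.root / row["path"]
            if not fp.exists():
                raise ConfigError(f"manifest entry missing on disk: {fp}")
            if verify and row["checksum"] and sha256_file(fp) != row["checksum"]:
                raise ConfigError(f"checksum mismatch for {fp}")
        return m

    def path_for(self, subject, scan, role, reader=None) -> Path:
        sel = self.frame[(self.frame["role"] == role)
                         & (self.frame["subject"].astype(str) == str(subject))
                         & (self.frame["scan"].astype(str) == str(scan))]
        if reader is not None:
            sel = sel[sel["reader"].astype(str) == str(reader)]
        if len(sel) != 1:
            raise ConfigError(
                f"expected exactly one manifest entry for role={role}, "
                f"subject={subject}, scan={scan}, reader={reader}; "
                f"found {len(sel)}")
        return self.root / sel.iloc[0]["path"]

    def singleton(self, role: str) -> Path:
        sel = self.frame[self.frame["role"] == role]
        if len(sel) != 1:
            raise ConfigError(f"expected one {role} entry, found {len(sel)}")
        return self.root / sel.iloc[0]["path"]

    def index_tuples(self) -> list[tuple[int, int]]:
        img = self.frame[self.frame["role"] == "mse"]
        return sorted({(int(r["subject"]), int(r["scan"]))
                       for _, r in img.iterrows()})

    def readers(self) -> list[int]:
        masks = self.frame[self.frame["role"] == "mask_nerve"]
        return sorted({int(r) for r in masks["reader"].unique()})


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------


class RunConfig(BaseModel):
    """Validated configuration of a full pipeline run.

    Unknown keys are rejected; the canonical JSON serialisation is hashed
    into every artefact for provenance.
    """

    model_config = ConfigDict(extra="forbid")

    n_subjects: int = Field(21, ge=2)
    n_scans: int = Field(3, ge=2)
    n_readers: int = Field(2, ge=2)
    noise_sigma: float = Field(5.0, ge=0)
    boundary_flip_prob: float = Field(0.15, ge=0, le=0.5)
    geometry: Optional[dict] = None
    analysis_slices: Optional[list[int]] = None
    fit_policy: Literal["fail", "drop"] = "drop"
    even_echo_rule: Literal["even-multiple", "even-index"] = "even-multiple"
    t2_bounds_ms: tuple[float, float] = relaxometry.DEFAULT_T2_BOUNDS_MS
    sem_flavor: Literal["agreement", "consistency"] = "agreement"
    ba_mode: Literal["simple", "repeated"] = "repeated"
    seed: int = 0

    def acquisition_geometry(self) -> AcquisitionGeometry:
        if self.geometry is None:
            return AcquisitionGeometry()
        return AcquisitionGeometry.from_dict(self.geometry)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_provenance(out_dir: Path | str, config: RunConfig) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = out / "provenance.json"
    p.write_text(json.dumps({"config_hash": config.config_hash(),
                             "config": config.model_dump(mode="json")},
                            indent=1))
    return p


def read_provenance_hash(dir_path: Path | str) -> str:
    p = Path(dir_path) / "provenance.json"
    if not p.exists():
        raise ConfigError(f"no provenance.json in {dir_path}")
    return json.loads(p.read_text())["config_hash"]


# --------------------------------------------------------------------------
# Biomarker extraction (fit stage)
# --------------------------------------------------------------------------


def extract_biomarkers(mse: MultiEchoStack, pair: MTPair,
                       ref_nerve: RoiMask, ref_muscle: RoiMask,
                       config: RunConfig) -> dict:
    """All five biomarkers for one (subject, scan, reader) image set.

    The reader's reference-grid masks are transferred (nearest neighbour)
    onto the MSE and MT grids; T2/PSD come from six slice-wise fits on the
    MSE stack, normalized PSD from the nerve/muscle six-slice PSD ratio,
    MTR from the MT pair, and CSA from the reference-grid mask averaged
    over the reference analysis slices.
    """
    nerve_mse = relaxometry.transfer_mask(ref_nerve, mse.grid)
    muscle_mse = relaxometry.transfer_mask(ref_muscle, mse.grid)
    nerve_mt = relaxometry.transfer_mask(ref_nerve, pair.grid)

    fit_kwargs = dict(policy=config.fit_policy,
                      even_rule=config.even_echo_rule,
                      t2_bounds=tuple(config.t2_bounds_ms))
    slices_mse = (config.analysis_slices
                  or mse.grid.central_slices())
    nerve_fit = relaxometry.nerve_t2_psd(mse, nerve_mse,
                                         analysis_slices=slices_mse,
                                         **fit_kwargs)
    muscle_fit = relaxometry.nerve_t2_psd(mse, muscle_mse,
                                          analysis_slices=slices_mse,
                                          **fit_kwargs)
    npsd = relaxometry.normalized_psd(nerve_fit.psd, muscle_fit.psd)
    mtr = mti.nerve_mtr(pair, nerve_mt)
    csa = float(np.mean([relaxometry.csa_from_mask(ref_nerve, i)
                         for i in ref_nerve.grid.central_slices()]))
    return {"t2_ms": nerve_fit.t2_ms, "psd": nerve_fit.psd,
            "psd_normalized": npsd, "mtr_percent": mtr.mtr_percent,
            "csa_mm2": csa}


def analyze_cohort_images(truth: CohortTruth, config: RunConfig
                          ) -> pd.DataFrame:
    """In-memory end-to-end pipeline: render, segment, fit, tabulate.

    Renders every (subject, scan) image set at the configured geometry and
    noise level, perturbs the reference masks per reader, and extracts all
    biomarkers. Returns the per-(subject, scan, reader) measurement frame.
    """
    geometry = config.acquisition_geometry()
    rows = []
    for s in range(truth.n_subjects):
        for t in range(truth.n_scans):
            mse, _, _ = synthetic.render_mse_stack(
                truth, s, t, geometry, config.noise_sigma)
            pair = synthetic.render_mt_pair(
                truth, s, t, geometry, config.noise_sigma)
            _, ref_nerve, ref_muscle = synthetic.render_reference(
                truth, s, t, geometry, config.noise_sigma)
            mask_seed = int(synthetic._rng(
                truth.seed, synthetic._NS_MASK_PERTURB, s, t).integers(2**31))
            for r in range(truth.n_readers):
                nerve_r = synthetic.perturb_mask(
                    ref_nerve, r, config.boundary_flip_prob, mask_seed)
                muscle_r = synthetic.perturb_mask(
                    ref_muscle, r, config.boundary_flip_prob, mask_seed)
                row = {"subject": s, "scan": t, "reader": r}
                row.update(extract_biomarkers(mse, pair, nerve_r, muscle_r,
                                              config))
                rows.append(row)
    return pd.DataFrame(rows)


def analyze_dataset(manifest: Manifest, config: RunConfig) -> pd.DataFrame:
    """Fit stage over an on-disk dataset indexed by a manifest."""
    rows = []
    for s, t in manifest.index_tuples():
        mse = load_mse_stack(manifest.path_for(s, t, "mse"))
        pair = MTPair(*(load_volume(manifest.path_for(s, t, role))[0]
                        for role in ("mt_off", "mt_on")),
                      grid=load_volume(manifest.path_for(s, t, "mt_off"))[1])
        for r in manifest.readers():
            nerve = load_mask(manifest.path_for(s, t, "mask_nerve", r),
                              "nerve")
            muscle = load_mask(manifest.path_for(s, t, "mask_muscle", r),
                               "muscle")
            row = {"subject": s, "scan": t, "reader": r}
            row.update(extract_biomarkers(mse, pair, nerve, muscle, config))
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Reporting
# --------------------------------------------------------------------------

_DISPLAY_DECIMALS = {"mtr_percent": 2, "t2_ms": 2, "psd": 1,
                     "psd_normalized": 2, "csa_mm2": 1}
_BIOMARKER_TITLES = {"mtr_percent": "MTR (%)", "t2_ms": "T2 (ms)",
                     "psd": "PSD", "psd_normalized": "Normalized PSD",
                     "csa_mm2": "CSA (mm^2)"}


def format_icc_ci(icc: float, lo: float, hi: float) -> str:
    """Render an ICC with its CI as e.g. '0.81 (0.60–0.92)'."""
    return f"{icc:.2f} ({lo:.2f}–{hi:.2f})"


def _descriptives_grid(descriptives: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for bio, grp in descriptives.groupby("biomarker"):
        dec = _DISPLAY_DECIMALS.get(bio, 2)
        row = {"Parameter": _BIOMARKER_TITLES.get(bio, bio)}
        for _, rec in grp.iterrows():
            col = f"Scan {rec['scan']} / Reader {rec['reader']}"
            row[col] = f"{rec['mean']:.{dec}f} ± {rec['std']:.{dec}f}"
        rows.append(row)
    return pd.DataFrame(rows)


def plot_bland_altman(result: reliability.BlandAltmanResult, title: str,
                      path: Path | str) -> None:
    """Scatter of differences vs means with bias and LoA lines."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.differences, s=14, alpha=0.7,
               color="black")
    ax.axhline(result.bias, color="black", lw=1.5, label="bias")
    for loa in (result.loa_low, result.loa_high):
        ax.axhline(loa, color="grey", ls=":", lw=1.2)
    ax.set_xlabel("Mean of paired measurements")
    ax.set_ylabel("Difference")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(descriptives: pd.DataFrame,
                  reliability_df: pd.DataFrame,
                  ba_results: dict,
                  out_dir: Path | str,
                  config: RunConfig | None = None) -> Path:
    """Markdown report with descriptive and reliability tables + BA plots."""
    if reliability_df is None or len(reliability_df) == 0:
        raise ConfigError("no reliability results to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# Quantitative MRN reliability report", ""]
    if config is not None:
        lines += [f"Config hash: `{config.config_hash()}` "
                  f"(seed {config.seed})", ""]

    lines += ["## Descriptive statistics (mean ± SD)", ""]
    grid = _descriptives_grid(descriptives)
    lines += [grid.to_markdown(index=False), ""]

    lines += ["## Reliability (ICC, SEM, MDD)", ""]
    rows = []
    for bio, grp in reliability_df.groupby("biomarker", sort=False):
        inter = grp[grp["design"] == "interreader"].iloc[0]
        tr = grp[grp["design"] == "test-retest"]
        dec = _DISPLAY_DECIMALS.get(bio, 2)
        row = {
            "Parameter": _BIOMARKER_TITLES.get(bio, bio),
            "Interreader ICC": format_icc_ci(inter["icc"], inter["ci_low"],
                                             inter["ci_high"]),
        }
        for _, rec in tr.iterrows():
            row[f"Test-retest ICC (reader {rec['reader']})"] = format_icc_ci(
                rec["icc"], rec["ci_low"], rec["ci_high"])
        row["SEM interreader"] = f"{inter['sem']:.{dec}f}"
        row["SEM test-retest"] = f"{tr['sem'].mean():.{dec}f}"
        row["MDD interreader"] = f"{inter['mdd']:.{dec}f}"
        row["MDD test-retest"] = f"{tr['mdd'].mean():.{dec}f}"
        rows.append(row)
    lines += [pd.DataFrame(rows).to_markdown(index=False), ""]

    lines += ["## Bland–Altman agreement", ""]
    for (bio, design), result in ba_results.items():
        png = out / f"bland_altman_{bio}_{design}.png"
        plot_bland_altman(result,
                          f"{_BIOMARKER_TITLES.get(bio, bio)} — {design}",
                          png)
        lines += [f"- {_BIOMARKER_TITLES.get(bio, bio)} ({design}): "
                  f"bias {result.bias:.3g}, LoA "
                  f"[{result.loa_low:.3g}, {result.loa_high:.3g}] "
                  f"(![plot]({png.name}))"]
    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report


# --------------------------------------------------------------------------
# CLI
# --------------------------------------------------------------------------


def _config_from_options(config_path, **overrides) -> RunConfig:
    base = {}
    if config_path:
        base = json.loads(Path(config_path).read_text())
    base.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**base)


_shared_options = [
    click.option("--config", "config_path", type=click.Path(exists=True),
                 default=None, help="JSON run configuration."),
    click.option("--seed", type=int, default=None),
    click.option("--subjects", "n_subjects", type=int, default=None),
    click.option("--scans", "n_scans", type=int, default=None),
    click.option("--readers", "n_readers", type=int, default=None),
    click.option("--noise-sigma", type=float, default=None),
    click.option("--sem-flavor", type=click.Choice(
        ["agreement", "consistency"]), default=None),
    click.option("--ba-mode", type=click.Choice(["simple", "repeated"]),
                 default=None),
]


def _with_shared(f):
    for opt in reversed(_shared_options):
        f = opt(f)
    return f


@click.group()
def main():
    """Quantitative MR-neurography pipeline (synthetic data edition)."""
    logging.basicConfig(level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")


@main.command()
@_with_shared
@click.option("--out", "out_dir", type=click.Path(), required=True)
def simulate(config_path, out_dir, **overrides):
    """Generate a synthetic dataset (images, masks, truth, manifest)."""
    cfg = _config_from_options(config_path, **overrides)
    manifest = synthetic.generate_dataset(
        out_dir, n_subjects=cfg.n_subjects, n_scans=cfg.n_scans,
        n_readers=cfg.n_readers, geometry=cfg.acquisition_geometry(),
        noise_sigma=cfg.noise_sigma,
        boundary_flip_prob=cfg.boundary_flip_prob, seed=cfg.seed)
    write_provenance(out_dir, cfg)
    click.echo(f"dataset written: {manifest}")


@main.command()
@_with_shared
@click.option("--data", "data_dir", type=click.Path(exists=True),
              required=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def fit(config_path, data_dir, out_dir, **overrides):
    """Estimate all biomarkers from an on-disk dataset."""
    cfg = _config_from_options(config_path, **overrides)
    manifest = Manifest.load(Path(data_dir) / "manifest.csv")
    df = analyze_dataset(manifest, cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "biomarkers.csv", index=False)
    write_provenance(out, cfg)
    click.echo(f"biomarkers written: {out / 'biomarkers.csv'}")


@main.command("reliability")
@_with_shared
@click.option("--biomarkers", "biomarkers_csv", type=click.Path(exists=True),
              required=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def reliability_cmd(config_path, biomarkers_csv, out_dir, **overrides):
    """Reliability suite (ICC/SEM/MDD/Bland-Altman) on a biomarker CSV."""
    cfg = _config_from_options(config_path, **overrides)
    df = pd.read_csv(biomarkers_csv)
    rel, ba, desc = reliability.analyze_cohort(
        df, sem_flavor=cfg.sem_flavor, ba_mode=cfg.ba_mode)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rel.to_csv(out / "reliability.csv", index=False)
    ba_rows = [{"biomarker": bio, "design": design, "bias": r.bias,
                "sd_diff": r.sd_diff, "loa_low": r.loa_low,
                "loa_high": r.loa_high, "n_differences": r.differences.size}
               for (bio, design), r in ba.items()]
    pd.DataFrame(ba_rows).to_csv(out / "bland_altman.csv", index=False)
    desc.to_csv(out / "descriptives.csv", index=False)
    write_provenance(out, cfg)
    click.echo(f"reliability written: {out / 'reliability.csv'}")


@main.command()
@_with_shared
@click.option("--results", "results_dir", type=click.Path(exists=True),
              required=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def report(config_path, results_dir, out_dir, **overrides):
    """Render the markdown report from a reliability results directory."""
    cfg = _config_from_options(config_path, **overrides)
    results = Path(results_dir)
    if read_provenance_hash(results) != cfg.config_hash():
        raise ConfigError(
            "provenance mismatch: the results were produced with a "
            "different configuration")
    rel = pd.read_csv(results / "reliability.csv")
    desc = pd.read_csv(results / "descriptives.csv")
    # reconstruct BA results from the stored per-difference data is not
    # needed for the tables; re-plot from the summary CSV
    ba_df = pd.read_csv(results / "bland_altman.csv")
    ba = {}
    for _, row in ba_df.iterrows():
        ba[(row["biomarker"], row["design"])] = reliability.BlandAltmanResult(
            bias=row["bias"], sd_diff=row["sd_diff"],
            loa_low=row["loa_low"], loa_high=row["loa_high"],
            differences=np.array([]), means=np.array([]),
            repeated=cfg.ba_mode == "repeated")
    path = render_report(desc, rel, ba, out_dir, config=cfg)
    click.echo(f"report written: {path}")


@main.command("run-all")
@_with_shared
@click.option("--out", "out_dir", type=click.Path(), required=True)
def run_all(config_path, out_dir, **overrides):
    """simulate -> fit -> reliability -> report, chained."""
    cfg = _config_from_options(config_path, **overrides)
    out = Path(out_dir)
    data_dir = out / "dataset"
    synthetic.generate_dataset(
        data_dir, n_subjects=cfg.n_subjects, n_scans=cfg.n_scans,
        n_readers=cfg.n_readers, geometry=cfg.acquisition_geometry(),
        noise_sigma=cfg.noise_sigma,
        boundary_flip_prob=cfg.boundary_flip_prob, seed=cfg.seed)
    write_provenance(data_dir, cfg)
    manifest = Manifest.load(data_dir / "manifest.csv")
    df = analyze_dataset(manifest, cfg)
    df.to_csv(out / "biomarkers.csv", index=False)
    rel, ba, desc = reliability.analyze_cohort(
        df, sem_flavor=cfg.sem_flavor, ba_mode=cfg.ba_mode)
    rel.to_csv(out / "reliability.csv", index=False)
    desc.to_csv(out / "descriptives.csv", index=False)
    write_provenance(out, cfg)
    path = render_report(desc, rel, ba, out / "report", config=cfg)
    click.echo(f"report written: {path}")


if __name__ == "__main__":
    main()
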