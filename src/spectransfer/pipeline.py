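"""End-to-end seeded experiment: simulate, split, transfer, classify, map.

``run_experiment`` reproduces the full study design on synthetic data:

1. generate 144 paired master/slave spectra (48 per species),
2. SPXY-split the samples ~2:1 into training and prediction sets,
3. trace the standard-set sizing curve (mean spectral angle vs k) for each
   transfer method,
4. fit PDS / SST / ATLD on their default standard-set sizes (15 / 10 / 20)
   and report before/after spectral angles and correlations,
5. train PLS-DA and SVM on master training spectra and compare their
   accuracy on the slave prediction set before and after each transfer,
6. build spliced cubes at ratios 0.5:1:2, 1:1:1 and 2:1:1 and report
   pixel-proportion recovery with and without the SST transfer,

writing four CSV reports, PNG adulteration maps and a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate
from .classify import before_after_comparison, evaluate, fit_plsda, fit_svm
from .datasets import SpectrumSet
from .mapping import classify_cube, proportions, render_map
from .sampling import (SplitResult, TransferDiagnostics, select_standard_samples,
                       size_standard_set, spxy_split)
from .transfer import (ATLDTransfer, PDSTransfer, SSTTransfer, common_grid,
                       cv_select_components, resample_to_grid)

__all__ = ["ExperimentConfig", "RunManifest", "run_experiment"]

log = logging.getLogger("spectransfer")


@dataclass
class ExperimentConfig:
    """Seeded configuration of the synthetic transfer experiment."""

    seed: int = 0
    n_per_class: int = 48
    train_fraction: float = 2 / 3
    standard_sizes: dict = field(
        default_factory=lambda: {"pds": 15, "sst": 10, "atld": 20}
    )
    pds_window_halfwidth: int = 12        # window size 25
    pds_components: int = 6
    sst_components: int = 6
    atld_factors: int = 2
    select_sst_components: bool = False   # 5-fold CV over sst_grid instead
    sst_grid: tuple = (1, 2, 3, 4, 5, 6, 7, 8)
    atld_grid: tuple = (1, 2, 3, 4)
    sizing_k_grid: tuple = (2, 3, 5, 8, 10, 15, 20, 25, 30)
    plsda_max_components: int = 10
    svm_C_grid: tuple = (1.0, 10.0, 100.0)
    svm_gamma_grid: tuple = (0.01, 0.1, 1.0)
    cube_ratios: tuple = ((0.5, 1.0, 2.0), (1.0, 1.0, 1.0), (2.0, 1.0, 1.0))
    cube_shape: tuple = (60, 60)
    cube_noise_sd: float = 0.003
    output_dir: str = "spectransfer_run"

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of one experiment run, sufficient to reproduce it exactly."""

    config_hash: str
    seed: int
    artifacts: dict
    version: str

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _prepare_data(config: ExperimentConfig):
    """Simulate, align to the common grid and SPXY-split."""
    master_view, slave_view = simulate.generate_paired_sets(
        n_per_class=config.n_per_class, seed=config.seed
    )
    grid = common_grid(master_view, slave_view)
    master = resample_to_grid(master_view, grid)
    slave = resample_to_grid(slave_view, grid)
    n_train = int(round(config.train_fraction * master.n_samples))
    split = spxy_split(master.spectra, master.labels, n_train)
    return master, slave, split


def _fit_transfers(config, master, slave, split):
    """Fit PDS/SST/ATLD on their default standard-set sizes."""
    Xm, Xs = master.spectra, slave.spectra
    sizes = config.standard_sizes
    std = {
        name: select_standard_samples(split, int(k)) for name, k in sizes.items()
    }
    sst_ncomp = config.sst_components
    atld_nfac = config.atld_factors
    reports = {}
    if config.select_sst_components:
        rep = cv_select_components("sst", Xm[std["sst"]], Xs[std["sst"]],
                                   config.sst_grid, seed=config.seed)
        sst_ncomp = int(rep.chosen["n_components"])
        reports["sst"] = rep
        rep = cv_select_components("atld", Xm[std["atld"]], Xs[std["atld"]],
                                   config.atld_grid, seed=config.seed)
        atld_nfac = int(rep.chosen["n_factors"])
        reports["atld"] = rep
    transfers = {
        "PDS": PDSTransfer(
            master.select(std["pds"]), Xs[std["pds"]],
            config.pds_window_halfwidth,
            min(config.pds_components, len(std["pds"]) - 1)).fit(),
        "SST": SSTTransfer(master.select(std["sst"]), Xs[std["sst"]],
                           min(sst_ncomp, len(std["sst"]) - 1)).fit(),
        "ATLD": ATLDTransfer(master.select(std["atld"]), Xs[std["atld"]],
                             atld_nfac).fit(),
    }
    return transfers, std, reports


def _sizing_table(config, master, slave, split) -> pd.DataFrame:
    """Mean held-out spectral angle versus standard-set size per method."""
    Xm, Xs = master.spectra, slave.spectra
    order = split.train_indices
    heldout = split.prediction_indices
    factories = {
        "PDS": lambda a, b: PDSTransfer(
            a, b, config.pds_window_halfwidth,
            min(config.pds_components, max(1, a.shape[0] - 1))).fit(),
        "SST": lambda a, b: SSTTransfer(
            a, b, min(config.sst_components, max(1, a.shape[0] - 1))).fit(),
        "ATLD": lambda a, b: ATLDTransfer(a, b, config.atld_factors).fit(),
    }
    frames = []
    for name, factory in factories.items():
        table, best_k = size_standard_set(
            Xm[order], Xs[order], factory, config.sizing_k_grid,
            Xm[heldout], Xs[heldout],
        )
        table.insert(0, "method", name)
        table["best_k"] = best_k
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def _transfer_table(master, slave, split, transfers) -> pd.DataFrame:
    """Before/after spectral angle and correlation on held-out samples."""
    idx = split.prediction_indices
    Xm, Xs = master.spectra[idx], slave.spectra[idx]
    rows = []
    before = TransferDiagnostics.compare(Xm, Xs)
    rows.append(("No", 0, before.mean_angle_deg, before.mean_correlation))
    for name, res in transfers.items():
        after = TransferDiagnostics.compare(Xm, res.transform(Xs))
        n_std = getattr(res, "n_standards", None)
        rows.append((name, np.nan if n_std is None else n_std,
                     after.mean_angle_deg, after.mean_correlation))
    return pd.DataFrame(
        rows, columns=["method", "n_standards", "mean_angle_deg",
                       "mean_correlation"]
    )


def run_experiment(config: ExperimentConfig | None = None) -> RunManifest:
    """Execute all stages and write reports under ``config.output_dir``."""
    from . import __version__

    config = config or ExperimentConfig()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    stage = "generate/split"
    try:
        master, slave, split = _prepare_data(config)

        stage = "standard-set sizing"
        sizing = _sizing_table(config, master, slave, split)
        sizing_path = out / "standard_set_sizing.csv"
        sizing.to_csv(sizing_path, index=False)
        artifacts["sizing_table"] = str(sizing_path)

        stage = "transfer fitting"
        transfers, std, cv_reports = _fit_transfers(config, master, slave, split)
        ttable = _transfer_table(master, slave, split, transfers)
        ttable["n_standards"] = ["0"] + [
            str(config.standard_sizes[k.lower()]) for k in transfers
        ]
        ttable_path = out / "transfer_comparison.csv"
        ttable.to_csv(ttable_path, index=False)
        artifacts["transfer_table"] = str(ttable_path)

        stage = "classification"
        tr, te = split.train_indices, split.prediction_indices
        plsda = fit_plsda(master.spectra[tr], master.labels[tr],
                          config.plsda_max_components, seed=config.seed)
        svm = fit_svm(master.spectra[tr], master.labels[tr],
                      config.svm_C_grid, config.svm_gamma_grid, seed=config.seed)
        comparison = before_after_comparison(
            {"PLS-DA": plsda, "SVM": svm},
            slave.spectra[te], slave.labels[te],
            {"No": None, **transfers},
        )
        acc_path = out / "discrimination_accuracy.csv"
        comparison.to_csv(acc_path, index=False)
        artifacts["accuracy_table"] = str(acc_path)

        stage = "cube mapping"
        rows = []
        slave_instrument = simulate.default_slave(noise_sd=config.cube_noise_sd)
        for r_i, ratio in enumerate(config.cube_ratios):
            cube = simulate.generate_spliced_cube(
                proportions=ratio, shape=tuple(config.cube_shape),
                slave=slave_instrument, seed=config.seed + 1000 + r_i,
            )
            label = "_".join(f"{v:g}" for v in ratio)
            for use_transfer, tag in ((None, "no_transfer"),
                                      (transfers["SST"], "sst")):
                lmap = classify_cube(cube, use_transfer, svm,
                                     grid_nm=master.wavelengths_nm)
                report = proportions(lmap, cube)
                png = out / f"map_ratio_{label}_{tag}.png"
                render_map(lmap, png)
                artifacts[f"map_{label}_{tag}"] = str(png)
                for _, rec in report.table.iterrows():
                    rows.append((label, tag, rec["class"],
                                 100 * rec["predicted_fraction"],
                                 100 * rec["truth_fraction"],
                                 100 * rec["abs_deviation"]))
        prop = pd.DataFrame(rows, columns=[
            "ratio", "transfer", "class", "predicted_pct", "truth_pct",
            "abs_deviation_pct",
        ])
        prop_path = out / "proportion_recovery.csv"
        prop.to_csv(prop_path, index=False)
        artifacts["proportion_table"] = str(prop_path)
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage '{stage}': {exc}") from exc

    config.to_yaml(out / "config.yaml")
    artifacts["config"] = str(out / "config.yaml")
    manifest = RunManifest(config.digest(), config.seed, artifacts, __version__)
    manifest.to_json(out / "manifest.json")
    log.info("experiment complete; reports in %s", out)
    return manifest
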