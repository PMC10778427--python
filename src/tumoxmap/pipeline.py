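"""End-to-end orchestration: simulate -> fit -> map -> target -> stats.

A :class:`RunConfig` (YAML-serialisable) drives the whole chain on a
synthetic phantom, writing stage artifacts (NIfTI maps, CSV tables,
stats JSON, plots) under a run directory together with a manifest of
parameters and content hashes, so a config + seed reproduce a run
bit-for-bit for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dsc_vsi, phantom, qbold, stats_report, targeting, voi_analysis
from .nifti_io import save_sidecar, save_volume

__all__ = ["RunConfig", "run"]

STAGES = ("simulate", "qbold", "perfusion", "voi", "target", "histology", "stats")


@dataclass
class RunConfig:
    """Serializable configuration of a full phantom pipeline run."""

    seed: int = 0
    out_dir: str = "runs/demo"
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    noise_model: str = "gaussian"
    noise_sigma: float = 0.0
    taus_ms: tuple[float, ...] = qbold.TAUS_MS_DEFAULT
    te_ms: float = 74.0
    dsc_tr_s: float = 1.5
    dsc_te_gre_ms: float = 18.6
    dsc_te_se_ms: float = 69.0
    dsc_n_volumes: int = 90
    b_values: tuple[float, ...] = (0.0, 10.0, 1000.0)
    qbold_method: str = "loglinear"
    residual_frac: float = 0.05
    high_pct: float = 80.0
    low_pct: float = 20.0
    min_cluster_voxels: int = 9
    max_targets: int = 4
    neighborhood: str = "cube27"
    coupling_strength: float = 1.0
    coupling_noise: float = 0.0
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")
        if self.qbold_method not in ("loglinear", "nls", "nonlinear"):
            raise ValueError(f"unknown qbold method {self.qbold_method!r}")
        if self.neighborhood not in ("cube27", "ten"):
            raise ValueError("neighborhood must be 'cube27' or 'ten'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("grid_shape", "taus_ms", "b_values", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Stage outputs are plain files (NIfTI/CSV/JSON); each stage consumes
    only the in-memory results of the previous ones plus the config.
    The manifest records the config, software version, and a content
    hash per written artifact.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    written: dict[str, str] = {}
    log: list[str] = []

    spec = phantom.PhantomSpec(
        grid_shape=tuple(config.grid_shape),
        noise=phantom.NoiseSpec(model=config.noise_model, sigma=config.noise_sigma),
        seed=config.seed,
    )
    truth = phantom.build_phantom(spec)
    contra_wm = truth.region_mask("contra_WM")
    brain = truth.brain_mask

    ase = dsc = dwi = None
    if "simulate" in config.stages:
        ase = phantom.simulate_flair_ase(truth, taus_ms=config.taus_ms, te_ms=config.te_ms)
        dsc = phantom.simulate_dsc(
            truth,
            tr_s=config.dsc_tr_s,
            te_gre_ms=config.dsc_te_gre_ms,
            te_se_ms=config.dsc_te_se_ms,
            n_volumes=config.dsc_n_volumes,
        )
        dwi = phantom.simulate_dwi(truth, b_values=config.b_values)
        written["labels.nii.gz"] = str(
            save_volume(out / "labels.nii.gz", truth.label_volume.astype(np.int16))
        )
        written["ase.nii.gz"] = str(save_volume(out / "ase.nii.gz", ase.data))
        save_sidecar(out / "ase.json", {"taus_ms": list(config.taus_ms), "TE_ms": config.te_ms})
        written["dsc_gre.nii.gz"] = str(save_volume(out / "dsc_gre.nii.gz", dsc.gre))
        written["dsc_se.nii.gz"] = str(save_volume(out / "dsc_se.nii.gz", dsc.se))
        written["dwi.nii.gz"] = str(save_volume(out / "dwi.nii.gz", dwi))
        (out / "phantom_spec.json").write_text(spec.to_json())
        log.append(f"simulate: phantom {config.grid_shape}, {int(brain.sum())} brain voxels")

    maps = None
    if "qbold" in config.stages:
        if ase is None:
            raise ValueError("qbold stage requires the simulate stage")
        maps = qbold.fit_qbold(
            ase,
            method=config.qbold_method,
            thresholds=qbold.FailureThresholds(residual_frac=config.residual_frac),
        )
        for name, vol in (
            ("R2prime", maps.R2prime), ("DBV", maps.DBV), ("OEF", maps.OEF),
            ("error_mask", maps.error_mask.astype(np.uint8)),
        ):
            written[f"{name}.nii.gz"] = str(save_volume(out / f"{name}.nii.gz", vol))
        log.append(f"qbold: {int(maps.error_mask[brain].sum())} failure voxels in brain")

    perf = None
    if "perfusion" in config.stages:
        if dsc is None:
            raise ValueError("perfusion stage requires the simulate stage")
        ref_mask = brain & (truth.parameter_maps["CBV_true"] > 0) & (
            truth.parameter_maps["leakage_K2"] == 0
        )
        perf = dsc_vsi.perfusion_pipeline(
            dsc, dwi, np.asarray(config.b_values), contra_wm,
            brain_mask=brain, reference_mask=ref_mask,
        )
        for name, vol in (
            ("CBV", perf.CBV), ("vessel_size", perf.vessel_size),
            ("K2", perf.K2), ("ADC", perf.ADC),
        ):
            written[f"{name}.nii.gz"] = str(save_volume(out / f"{name}.nii.gz", vol))
        log.append("perfusion: CBV/vessel-size maps computed")

    if "voi" in config.stages and maps is not None:
        voi_set = voi_analysis.VoiMaskSet(
            masks={n: truth.region_mask(n) for n in voi_analysis.ALL_VOI_NAMES
                   if truth.region_mask(n).any()}
        )
        metric_maps = {"R2prime": maps.R2prime, "DBV": maps.DBV, "OEF": maps.OEF}
        if perf is not None:
            metric_maps.update(CBV=perf.CBV, vessel_size=perf.vessel_size)
        summary = voi_analysis.voi_summary(metric_maps, voi_set, maps.error_mask)
        summary.to_csv(out / "voi_summary.csv", index=False)
        written["voi_summary.csv"] = str(out / "voi_summary.csv")

        gm_curve = voi_analysis.voi_curve(
            ase, truth.region_mask("contra_GM"), maps.error_mask, voi_name="contra_GM"
        )
        curves = [gm_curve]
        for name in voi_analysis.TUMOR_VOI_NAMES:
            m = truth.region_mask(name)
            if (m & ~maps.error_mask).any():
                curves.append(
                    voi_analysis.voi_curve(ase, m, maps.error_mask, gm_curve, voi_name=name)
                )
        rows = []
        for c in curves:
            for t, mu, sd in zip(c.taus_ms, c.mean_ln_signal, c.sd_ln_signal):
                rows.append(dict(voi=c.voi_name, tau_ms=t, mean_ln_signal=mu, sd_ln_signal=sd))
        pd.DataFrame(rows).to_csv(out / "voi_curves.csv", index=False)
        written["voi_curves.csv"] = str(out / "voi_curves.csv")
        log.append(f"voi: {len(curves)} curves, summary over {len(voi_set.masks)} masks")

    targets: list = []
    if "target" in config.stages and maps is not None and perf is not None:
        search = np.zeros(truth.label_volume.shape, dtype=bool)
        for name in ("nonenhancing", "enhancing", "necrosis"):
            search |= truth.region_mask(name)
        metric_maps = {"OEF": maps.OEF, "CBV": perf.CBV, "vessel_size": perf.vessel_size}
        clusters = {}
        for metric, vol in metric_maps.items():
            cl = []
            for polarity in ("high", "low"):
                crit = targeting.ClusterCriteria(
                    metric=metric, polarity=polarity,
                    high_pct=config.high_pct, low_pct=config.low_pct,
                    min_voxels=config.min_cluster_voxels,
                )
                cl.extend(targeting.find_clusters(vol, crit, search, maps.error_mask))
            clusters[metric] = cl
        targets = targeting.prioritize(clusters, max_targets=config.max_targets)
        rows = []
        for t in targets:
            t.voi_label = {v: k for k, v in truth.labels.items()}.get(
                int(truth.label_volume[t.center_voxel]), "unknown"
            )
            vals = targeting.extract_target_values(
                metric_maps, t, maps.error_mask, mode=config.neighborhood
            )
            world = (np.asarray(ase.affine) @ np.array([*t.center_voxel, 1.0]))[:3]
            rows.append(
                dict(cluster_id=t.cluster_id, rank=t.priority_rank,
                     x=t.center_voxel[0], y=t.center_voxel[1], z=t.center_voxel[2],
                     wx=world[0], wy=world[1], wz=world[2],
                     voi_label=t.voi_label,
                     criteria=";".join(f"{m}:{p}" for m, p in t.defining_criteria),
                     **vals)
            )
        pd.DataFrame(rows).to_csv(out / "targets.csv", index=False)
        written["targets.csv"] = str(out / "targets.csv")
        log.append(f"target: {len(targets)} biopsy targets")

    histo = None
    if "histology" in config.stages and targets:
        histo = phantom.simulate_histology(
            truth, targets,
            coupling=phantom.HistologyCoupling(
                strength=config.coupling_strength, noise=config.coupling_noise
            ),
            seed=config.seed,
        )
        histo.to_csv(out / "histology.csv", index=False)
        written["histology.csv"] = str(out / "histology.csv")
        log.append(f"histology: {len(histo)} samples")

    if "stats" in config.stages and histo is not None and targets:
        mri_rows = pd.DataFrame(
            [dict(sample_id=f"S{i + 1:02d}", **t.mri_values) for i, t in enumerate(targets)]
        )
        paired = histo.merge(mri_rows, on="sample_id")
        paired.to_csv(out / "paired.csv", index=False)
        written["paired.csv"] = str(out / "paired.csv")
        stats_report.report(paired, out_dir=out)
        written["stats.json"] = str(out / "stats.json")
        log.append("stats: report written")

    manifest = {
        "config_digest": config.digest(),
        "config": yaml.safe_load(config.to_yaml()),
        "stages_run": [s for s in STAGES if s in config.stages],
        "artifacts": {k: _hash_file(Path(v)) for k, v in written.items()},
        "log": log,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
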