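"""Formats, configuration, provenance, and the end-to-end runner.

Tables are tidy long-format CSV with provenance (config hash + seed)
embedded as ``#``-prefixed header comments.  Statistic maps round-trip
through compressed ``.npz`` archives or, when requested, NIfTI volumes
(shape 1 x 1 x V, since voxel geometry is abstract) with a JSON label
sidecar.
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

from .design import AcquisitionSpec
from .glm import StatMap
from .pipeline import cohort_li_table, fit_cohort, heldout_for_pair
from .population import PopulationSpec, sample_population

__all__ = [
    "config_hash",
    "load_config",
    "save_config",
    "write_stat_map",
    "read_stat_map",
    "write_table",
    "read_table",
    "RunManifest",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
]


# ---------------------------------------------------------------- config

def _spec_to_dict(spec) -> dict:
    out = {}
    for f in dataclasses.fields(spec):
        v = getattr(spec, f.name)
        if isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out


def config_to_dict(population: PopulationSpec, acquisition: AcquisitionSpec) -> dict:
    return {"population": _spec_to_dict(population),
            "acquisition": _spec_to_dict(acquisition)}


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable config mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> tuple[PopulationSpec, AcquisitionSpec]:
    """Read a YAML or JSON config with ``population`` / ``acquisition`` blocks."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    pop_kwargs = dict(data.get("population", {}))
    for key in ("categories",):
        if key in pop_kwargs:
            pop_kwargs[key] = tuple(pop_kwargs[key])
    for key in ("true_li_means", "true_li_sd", "li_correlation", "overlap"):
        if key in pop_kwargs and isinstance(pop_kwargs[key], list):
            pop_kwargs[key] = np.asarray(pop_kwargs[key], dtype=float)
    pop = PopulationSpec(**pop_kwargs)
    acq = AcquisitionSpec(**data.get("acquisition", {}))
    return pop, acq


def save_config(population: PopulationSpec, acquisition: AcquisitionSpec, path) -> None:
    path = Path(path)
    data = config_to_dict(population, acquisition)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------- stat maps

def write_stat_map(stat_map: StatMap, path) -> None:
    """Write a StatMap to ``.npz`` (values + labels) or ``.nii``/``.nii.gz``
    (1 x 1 x V volume with a ``.json`` label sidecar)."""
    path = Path(path)
    if stat_map.hemispheres is None:
        raise ValueError("stat map must carry hemisphere labels for serialization")
    hemis = np.asarray(stat_map.hemispheres)
    for h in ("L", "R"):
        if not (hemis == h).any():
            raise ValueError(f"label table missing hemisphere {h!r}")
    if path.suffix == ".npz":
        np.savez_compressed(
            path, data=stat_map.data, df=stat_map.df, kind=stat_map.kind,
            name=stat_map.name, hemispheres=hemis.astype("U1"),
        )
        return
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.Nifti1Image(
            stat_map.data.reshape(1, 1, -1).astype(np.float64), affine=np.eye(4)
        )
        nib.save(img, path)
        sidecar = {"df": int(stat_map.df), "kind": stat_map.kind, "name": stat_map.name,
                   "hemispheres": hemis.tolist()}
        _sidecar_path(path).write_text(json.dumps(sidecar))
        return
    raise ValueError(f"unsupported stat-map format {path.suffix!r}")


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    raise ValueError(name)


def read_stat_map(path) -> StatMap:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return StatMap(
                data=z["data"], df=int(z["df"]), kind=str(z["kind"]),
                name=str(z["name"]), hemispheres=z["hemispheres"],
            )
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        sidecar = json.loads(_sidecar_path(path).read_text())
        return StatMap(
            data=np.asarray(img.dataobj).reshape(-1), df=int(sidecar["df"]),
            kind=sidecar["kind"], name=sidecar.get("name", ""),
            hemispheres=np.asarray(sidecar["hemispheres"]),
        )
    raise ValueError(f"unsupported stat-map format {path.suffix!r}")


# ---------------------------------------------------------------- tables

def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """CSV with ``#``-prefixed provenance header lines (config hash, seed)."""
    path = Path(path)
    lines = []
    for k, v in (provenance or {}).items():
        lines.append(f"# {k}: {v}")
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------- manifest

@dataclass
class RunManifest:
    """Index of per-subject statistic-map files for externally fitted data.

    maps: subject_id -> {(category, run_split): path}.
    """

    maps: dict[str, dict[tuple[str, str], str]]
    atlas_path: str | None = None
    seed: int = 0
    config_hash: str = ""

    def validate(self) -> None:
        missing = []
        for sid, entries in self.maps.items():
            for key, p in entries.items():
                if not Path(p).exists():
                    missing.append((sid, key, p))
        if missing:
            raise FileNotFoundError(f"manifest references missing files: {missing[:5]}")


# ---------------------------------------------------------------- pipeline

@dataclass
class PipelineConfig:
    population: PopulationSpec = field(default_factory=PopulationSpec)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    baselines: tuple[str, ...] = ("full", "heldout", "fixation")
    metrics: tuple[str, ...] = ("summed",)
    alpha: float = 0.001
    n_parcels: int = 10
    fdr_alpha: float = 0.05
    coupling_method: str = "spearman"
    pairwise_method: str = "pearson"
    category_pairs: tuple[tuple[str, str], ...] = (
        ("faces", "text"), ("objects", "text"), ("faces", "objects"),
    )

    @property
    def hash(self) -> str:
        return config_hash(
            {"population": _spec_to_dict(self.population),
             "acquisition": _spec_to_dict(self.acquisition),
             "baselines": list(self.baselines), "metrics": list(self.metrics),
             "alpha": self.alpha, "n_parcels": self.n_parcels,
             "fdr_alpha": self.fdr_alpha}
        )


@dataclass
class PipelineResult:
    li_table: pd.DataFrame
    pairwise: pd.DataFrame
    parcel_table: pd.DataFrame
    coupling: "object"
    report: str
    provenance: dict


def run_pipeline(config: PipelineConfig, seed: int = 0, out_dir=None) -> PipelineResult:
    """simulate -> fit -> selectivity -> laterality -> correlate.

    Deterministic for a fixed (config, seed); when ``out_dir`` is given,
    writes li_table.csv, pairwise.csv, parcel_li.csv, coupling.csv, and a
    text report, each embedding the config hash and seed.
    """
    from .glm import StatMap
    from .laterality import pairwise_li_correlation
    from .parcels import parcel_coupling, parcel_li_table, synthetic_homotopic_atlas

    try:
        rng = np.random.default_rng(seed)
        cohort = sample_population(config.population, rng)
        fit = fit_cohort(cohort, acq=config.acquisition, seed=rng)
    except Exception as exc:  # pragma: no cover - error tagging
        raise RuntimeError(f"[simulate/fit] {exc}") from exc

    try:
        table = cohort_li_table(
            fit, baselines=config.baselines, metrics=config.metrics, alpha=config.alpha
        )
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"[laterality] {exc}") from exc

    try:
        rows = []
        for cat_a, cat_b in config.category_pairs:
            for baseline in config.baselines:
                res = pairwise_li_correlation(
                    table, cat_a, cat_b, baseline=baseline,
                    metric=config.metrics[0], method=config.pairwise_method,
                )
                rows.append({"category_a": cat_a, "category_b": cat_b,
                             "scheme": baseline, "r": res.r, "p": res.p, "n": res.n})
            if "fixation" in config.baselines:
                res = pairwise_li_correlation(
                    table, cat_a, cat_b, baseline="fixation",
                    metric=config.metrics[0], method=config.pairwise_method,
                    residualize_on=heldout_for_pair(cat_a, cat_b),
                )
                rows.append({"category_a": cat_a, "category_b": cat_b,
                             "scheme": "fixation_residualized",
                             "r": res.r, "p": res.p, "n": res.n})
        pairwise = pd.DataFrame(rows)
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"[correlate] {exc}") from exc

    try:
        atlas = synthetic_homotopic_atlas(
            config.population.n_voxels_per_hemisphere, config.n_parcels
        )
        # parcel LIs from even runs, target (whole-ROI text LI) from odd runs
        maps_even = {
            sid: fit.subject_stat_map(
                i, _fixation_contrast(fit, "text", "even"), name="text_even"
            )
            for i, sid in enumerate(cohort.subject_ids)
        }
        parcel_tab = parcel_li_table(maps_even, atlas, metric=config.metrics[0])
        from .laterality import _select_li

        target = _select_li(table, "text", "fixation", "odd", config.metrics[0])
        coupling = parcel_coupling(
            parcel_tab, target, method=config.coupling_method,
            fdr_alpha=config.fdr_alpha, target_label="text_roi_odd",
        )
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"[couple] {exc}") from exc

    provenance = {"config_hash": config.hash, "seed": seed,
                  "n_undefined_li": table.attrs.get("n_undefined", 0)}
    report = _pipeline_report(pairwise, coupling, provenance)
    result = PipelineResult(
        li_table=table, pairwise=pairwise, parcel_table=parcel_tab,
        coupling=coupling, report=report, provenance=provenance,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(table, out / "li_table.csv", provenance)
        write_table(pairwise, out / "pairwise.csv", provenance)
        write_table(parcel_tab, out / "parcel_li.csv", provenance)
        write_table(coupling.table, out / "coupling.csv", provenance)
        (out / "report.txt").write_text(report)
    return result


def _fixation_contrast(fit, category: str, split: str):
    from .contrasts import build_domain_contrast

    return build_domain_contrast(category, "fixation", run_split=split,
                                 n_runs=fit.acq.n_runs)


def _pipeline_report(pairwise: pd.DataFrame, coupling, provenance: dict) -> str:
    lines = [
        "hemilat pipeline report",
        f"config hash: {provenance['config_hash']}  seed: {provenance['seed']}",
        f"undefined LIs excluded: {provenance['n_undefined_li']}",
        "",
        "Pairwise cross-subject LI correlations (cat A odd runs vs cat B even runs):",
    ]
    for _, row in pairwise.iterrows():
        lines.append(
            f"  {row['category_a']:>7s} vs {row['category_b']:<7s} "
            f"[{row['scheme']:<22s}] r = {row['r']:+.3f} (p = {row['p']:.2g}, n = {row['n']})"
        )
    lines.append("")
    lines.append(
        f"Parcel coupling with {coupling.target_label}: "
        f"{coupling.n_significant}/{len(coupling.table)} parcels significant "
        f"at FDR {coupling.fdr_alpha:g} ({coupling.method})"
    )
    return "\n".join(lines)
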