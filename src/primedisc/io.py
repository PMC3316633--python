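"""File formats, configuration and seed plumbing.

Events tables are tab-separated with a header; volumes are NIfTI-1 via
nibabel; fit results and group summaries are CSV; configuration is a YAML
key-value tree that round-trips losslessly.  One master seed fans out to
fixed per-stage child seeds so every stage is independently re-runnable.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .bold import VolumeSeries
from .design import DesignConfig
from .fitting import FitResult
from .simulate import BoldSpec, PlantedRegion, PopulationSpec

__all__ = [
    "EVENTS_COLUMNS",
    "read_events",
    "write_events",
    "save_volume",
    "load_volume",
    "fit_results_frame",
    "write_fit_results",
    "PipelineConfig",
    "load_config",
    "dump_config",
    "stage_seed",
]

EVENTS_COLUMNS = {
    "run": "int64",
    "trial": "int64",
    "onset_s": "float64",
    "stim_onset_s": "float64",
    "duration_s": "float64",
    "trial_type": "object",
    "prime": "object",
    "amount": "float64",
    "delay": "float64",
    "side_later": "object",
}

#: fixed stage indices for seed derivation
_STAGES = ("design", "participants", "choices", "visibility", "bold", "analysis")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from one master seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; one of {_STAGES}")
    ss = np.random.SeedSequence([int(master_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def write_events(events: pd.DataFrame, path) -> None:
    path = Path(path)
    missing = [c for c in EVENTS_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"events table missing columns {missing}")
    events.to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep="n/a")


def read_events(path) -> pd.DataFrame:
    """Read and validate a tab-separated events table.

    Schema violations raise with the offending column named; choice
    columns are optional (schedules have no choices yet).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    if df.shape[1] == 1:
        raise ValueError(
            f"{path.name}: expected tab-separated columns, got a single "
            f"column {df.columns[0]!r} (wrong delimiter?)"
        )
    missing = [c for c in EVENTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    for col, dtype in EVENTS_COLUMNS.items():
        try:
            df[col] = df[col].astype(dtype)
        except (ValueError, TypeError) as err:
            raise ValueError(
                f"{path.name}: column '{col}' not parseable as {dtype}: {err}"
            ) from None
    bad = ~df["trial_type"].isin(["TD", "PC"])
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(
            f"{path.name}: row {row}: invalid trial_type "
            f"{df.loc[row, 'trial_type']!r}"
        )
    return df


def save_volume(vol: VolumeSeries, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms((vol.voxel_size_mm,) * 3 + (vol.tr_s,))
    img.header["descrip"] = f"runs={vol.n_runs};vpr={vol.volumes_per_run}".encode()
    nib.save(img, str(path))


def load_volume(path, n_runs: int | None = None, mask=None) -> VolumeSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    desc = bytes(img.header["descrip"]).decode(errors="ignore")
    meta = dict(
        kv.split("=") for kv in desc.strip("\x00").split(";") if "=" in kv
    )
    n_runs = n_runs or int(meta.get("runs", 1))
    vpr = data.shape[-1] // n_runs
    voxel = float(img.header.get_zooms()[0])
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    if mask is None:
        mask = np.any(data != 0, axis=-1)
    return VolumeSeries(
        data=data,
        tr_s=tr,
        n_runs=n_runs,
        volumes_per_run=vpr,
        voxel_size_mm=voxel,
        mask=mask,
        affine=img.affine,
    )


def fit_results_frame(results: dict) -> pd.DataFrame:
    """Per-subject fit table (k, a, omega, SEs, logLik, AIC, BIC per model).

    ``results`` maps subject id -> dict with keys 'baseline', 'priming'
    (FitResult) and optionally 'comparison' (ModelComparison).
    """
    rows = []
    for sid, res in results.items():
        row = {"subject": sid}
        for model in ("baseline", "priming"):
            fr: FitResult = res[model]
            pre = "b_" if model == "baseline" else "p_"
            row[pre + "k"] = fr.params.k
            row[pre + "omega"] = fr.params.omega
            se = list(fr.std_errors)
            if model == "baseline":
                row["b_k_se"], row["b_omega_se"] = se
            else:
                row["p_a"] = fr.params.a
                row["p_k_se"], row["p_a_se"], row["p_omega_se"] = se
            row[pre + "loglik"] = fr.log_lik
            row[pre + "aic"] = fr.aic
            row[pre + "bic"] = fr.bic
            row[pre + "n_trials"] = fr.n_trials
        comp = res.get("comparison")
        if comp is not None:
            row["lr"] = comp.lr_statistic
            row["lr_p"] = comp.p_value
            row["delta_aic"] = comp.delta_aic
            row["delta_bic"] = comp.delta_bic
            row["preferred"] = comp.preferred
        rows.append(row)
    return pd.DataFrame(rows)


def write_fit_results(results: dict, path) -> None:
    fit_results_frame(results).to_csv(path, index=False)


@dataclasses.dataclass
class PipelineConfig:
    """Everything a full pipeline invocation needs, YAML round-trippable."""

    design: DesignConfig = dataclasses.field(default_factory=DesignConfig)
    population: PopulationSpec = dataclasses.field(default_factory=PopulationSpec)
    bold: BoldSpec = dataclasses.field(default_factory=BoldSpec)
    master_seed: int = 0
    output_dir: str = "primedisc_out"
    visibility_trials: int = 96
    visibility_d_prime: float = 0.0
    n_boot: int = 1000


def _asdict(obj):
    d = dataclasses.asdict(obj)

    def clean(v):
        if isinstance(v, tuple):
            return [clean(x) for x in v]
        if isinstance(v, list):
            return [clean(x) for x in v]
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, np.generic):
            return v.item()
        return v

    return clean(d)


def dump_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_asdict(config), fh, sort_keys=False)


def _build(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - names)
    if unknown:
        raise ValueError(f"unknown keys in {context}: {unknown}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(
                tuple(x) if isinstance(x, list) else x for x in v
            )
        kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Parse a YAML config; unknown keys raise, listing them."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(data) - names)
    if unknown:
        raise ValueError(f"unknown keys in config: {unknown}")
    kwargs = {}
    if "design" in data:
        kwargs["design"] = _build(DesignConfig, data["design"], "design")
    if "population" in data:
        kwargs["population"] = _build(PopulationSpec, data["population"], "population")
    if "bold" in data:
        bold = dict(data["bold"])
        regions = bold.pop("regions", ())
        bold_spec = _build(BoldSpec, bold, "bold")
        if regions:
            built = tuple(
                _build(PlantedRegion, dict(r), "bold.regions") for r in regions
            )
            bold_spec = dataclasses.replace(bold_spec, regions=built)
        kwargs["bold"] = bold_spec
    for key in (
        "master_seed",
        "output_dir",
        "visibility_trials",
        "visibility_d_prime",
        "n_boot",
    ):
        if key in data:
            kwargs[key] = data[key]
    return PipelineConfig(**kwargs)
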