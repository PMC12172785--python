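"""File formats: TSV for tables and sampled series, JSON for metadata.

All numeric TSV output uses 17 significant digits so every write→read
round-trip is lossless for float64. Column orders are fixed: region
columns follow the package region order, design columns follow the
design's input order ("faces" first). Time-series and design TSVs carry
a sidecar JSON (same path with .json extension) holding the sampling
metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bms import BMAResult, BMSResult
from .dcm import DCMResults
from .model_space import ModelSpace, NetworkStructure
from .regions import DEFAULT_REGIONS
from .simulate import BOLDTimeSeries, StimulusDesign

FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    pass


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc


# -- time series -----------------------------------------------------------

def write_timeseries_tsv(ts: BOLDTimeSeries, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(ts.y, columns=list(ts.regions.labels))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    meta = {"tr": ts.tr, "units": "a.u.", "n_scans": ts.n_scans}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_timeseries_tsv(path: str | Path) -> BOLDTimeSeries:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata file {sidecar} for {path}")
    meta = json.loads(sidecar.read_text())
    df = _read_tsv(path)
    expected = list(DEFAULT_REGIONS.labels)
    if list(df.columns) != expected:
        raise FormatError(f"{path}: columns {list(df.columns)} != {expected}")
    return BOLDTimeSeries(tr=float(meta["tr"]), y=df.to_numpy())


# -- designs ---------------------------------------------------------------

def write_design_tsv(design: StimulusDesign, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({name: design.inputs[name] for name in design.input_names})
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    _sidecar_path(path).write_text(json.dumps({"dt": design.dt}, indent=1))


def read_design_tsv(path: str | Path) -> StimulusDesign:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata file {sidecar} for {path}")
    meta = json.loads(sidecar.read_text())
    df = _read_tsv(path)
    return StimulusDesign(dt=float(meta["dt"]),
                          inputs={c: df[c].to_numpy() for c in df.columns})


# -- model space -----------------------------------------------------------

def write_model_space_json(space: ModelSpace, path: str | Path) -> None:
    doc = {"modulators": list(space.modulator_names),
           "structures": [s.to_dict() for s in space.structures]}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model_space_json(path: str | Path) -> ModelSpace:
    doc = json.loads(Path(path).read_text())
    structures = tuple(NetworkStructure.from_dict(d) for d in doc["structures"])
    return ModelSpace(structures=structures, modulator_names=tuple(doc["modulators"]))


# -- inversions ------------------------------------------------------------

def write_inversion_json(res: DCMResults, path: str | Path) -> None:
    doc = {
        "model_id": res.model_id,
        "labels": [list(lab) for lab in res.labels],
        "posterior_mean": res.posterior_mean.tolist(),
        "posterior_cov": res.posterior_cov.reshape(-1).tolist(),
        "free_energy": res.free_energy,
        "log_likelihood": res.log_likelihood,
        "aic": res.aic,
        "bic": res.bic,
        "n_params": res.n_params,
        "n_scans": res.n_scans,
        "h": res.h.tolist(),
        "converged": res.converged,
        "n_iter": res.n_iter,
        "f_trace": res.f_trace,
    }
    Path(path).write_text(json.dumps(doc))


def read_inversion_json(path: str | Path) -> DCMResults:
    doc = json.loads(Path(path).read_text())
    p = doc["n_params"]
    return DCMResults(
        model_id=doc["model_id"],
        labels=tuple(tuple(lab) for lab in doc["labels"]),
        posterior_mean=np.asarray(doc["posterior_mean"]),
        posterior_cov=np.asarray(doc["posterior_cov"]).reshape(p, p),
        free_energy=doc["free_energy"],
        log_likelihood=doc["log_likelihood"],
        aic=doc["aic"],
        bic=doc["bic"],
        n_params=p,
        n_scans=doc["n_scans"],
        h=np.asarray(doc["h"]),
        converged=doc["converged"],
        n_iter=doc["n_iter"],
        f_trace=doc["f_trace"],
    )


# -- tables ----------------------------------------------------------------

def write_table_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(Path(path), sep="\t", index=False, float_format=FLOAT_FMT)


def read_table_tsv(path: str | Path) -> pd.DataFrame:
    return _read_tsv(Path(path))


def write_bms_tsv(res: BMSResult, path: str | Path) -> None:
    df = pd.DataFrame({"model_id": res.model_ids,
                       "alpha": res.dirichlet_alpha,
                       "posterior_prob": res.expected_probs,
                       "exceedance_prob": res.exceedance_probs})
    write_table_tsv(df, path)
    meta = {"criterion": res.criterion, "draws": res.draws, "seed": res.seed,
            "winning_model": res.winning_model}
    _sidecar_path(Path(path)).write_text(json.dumps(meta, indent=1))


def write_bma_tsv(results: dict[str, BMAResult], path: str | Path) -> None:
    rows = []
    for sid, bma in results.items():
        for (matrix, src, tgt, inp), value in bma.params.items():
            rows.append(dict(session=sid, matrix=matrix, source=src, target=tgt,
                             input=inp, value=value))
    write_table_tsv(pd.DataFrame(rows), path)


# -- cohort directory layout ----------------------------------------------

def write_cohort(cohort, root: str | Path) -> None:
    """study/participant/session tree + covariates.tsv + manifest.json."""
    from .cohort import CohortDataset  # local import to avoid cycle
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for rec in cohort.records:
        d = root / rec.study / rec.participant / f"ses-{rec.session}"
        d.mkdir(parents=True, exist_ok=True)
        write_timeseries_tsv(rec.data, d / "bold.tsv")
        write_design_tsv(rec.design, d / "design.tsv")
    write_table_tsv(cohort.covariates(), root / "covariates.tsv")
    manifest = {
        "seed": cohort.seed,
        "noise_sd": cohort.noise_sd,
        "truth": _truth_to_dict(cohort.truth),
        "participant_params": {
            f"{study}/{pid}": _params_to_dict(p)
            for (study, pid), p in cohort.participant_params.items()
        },
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_cohort(root: str | Path):
    from .cohort import CohortDataset, GroundTruth, SessionRecord
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    cov = read_table_tsv(root / "covariates.tsv")
    records = []
    for _, row in cov.iterrows():
        d = root / str(row["study"]) / str(row["participant"]) / f"ses-{row['session']}"
        records.append(SessionRecord(
            study=str(row["study"]), participant=str(row["participant"]),
            session=int(row["session"]), hormone=str(row["hormone"]),
            data=read_timeseries_tsv(d / "bold.tsv"),
            design=read_design_tsv(d / "design.tsv")))
    truth = _truth_from_dict(manifest["truth"])
    params = {tuple(k.split("/")): _params_from_dict(v)
              for k, v in manifest["participant_params"].items()}
    return CohortDataset(records=records, truth=truth, participant_params=params,
                         noise_sd=manifest["noise_sd"], seed=manifest["seed"])


def _params_to_dict(p) -> dict:
    return {"a": p.a.tolist(), "b": {k: v.tolist() for k, v in p.b.items()},
            "c": p.c.tolist(), "eps_logdev": p.eps_logdev.tolist(),
            "tau_logdev": p.tau_logdev.tolist()}


def _params_from_dict(d):
    from .params import DCMParameters
    return DCMParameters(a=np.asarray(d["a"]),
                         b={k: np.asarray(v) for k, v in d["b"].items()},
                         c=np.asarray(d["c"]),
                         eps_logdev=np.asarray(d["eps_logdev"]),
                         tau_logdev=np.asarray(d["tau_logdev"]))


def _truth_to_dict(t) -> dict:
    return {"mean": _params_to_dict(t.mean), "sd_a": t.sd_a, "sd_b": t.sd_b,
            "sd_c": t.sd_c}


def _truth_from_dict(d):
    from .cohort import GroundTruth
    return GroundTruth(mean=_params_from_dict(d["mean"]), sd_a=d["sd_a"],
                       sd_b=d["sd_b"], sd_c=d["sd_c"])
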