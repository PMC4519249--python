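"""Configuration files, fixtures and tabular output.

Configs are JSON or YAML documents whose keys mirror the parameter dataclass
fields exactly (nested ``ti`` / ``kinetics`` / ``gn`` sections); unknown keys
are rejected with the offending name so typos cannot silently fall back to a
default.  Tabular outputs are TSV with ``#`` header lines recording the tool
version, a hash of the generating configuration and the seed, which makes any
output file traceable to an exact rerun.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .network import GN_SPECIES, BistabilityResult
from .params import (PROVENANCE, GNParams, ParameterError, PauseSite,
                     PromoterParams, RNAKinetics, TIConfig)
from .traffic import RateTable, TrafficResult

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
    "make_fixture",
    "write_tables",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class RunConfig:
    """Top-level bundle: traffic config plus optional kinetic/protein layers."""

    ti: TIConfig
    kinetics: RNAKinetics | None = None
    gn: GNParams | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d: dict[str, Any] = {"ti": dataclasses.asdict(self.ti), "seed": self.seed}
        if self.kinetics is not None:
            d["kinetics"] = dataclasses.asdict(self.kinetics)
        if self.gn is not None:
            d["gn"] = dataclasses.asdict(self.gn)
        return d

    def provenance_warnings(self) -> list[str]:
        """Names of placeholder-tagged parameters present in this bundle."""
        names = []
        if self.kinetics is not None or self.gn is not None:
            names = [k for k, v in PROVENANCE.items() if v == "placeholder"]
        return names


def _build(cls, data: dict, context: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ParameterError(
            f"{context}: unknown parameter(s) {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}")
    return cls(**data)


def _build_ti(data: dict) -> TIConfig:
    data = dict(data)
    for prom in ("pX", "pY"):
        if prom in data:
            sub = dict(data[prom])
            sub.setdefault("name", prom)
            data[prom] = _build(PromoterParams, sub, f"ti.{prom}")
        else:
            raise ParameterError(f"ti: missing required section {prom!r}")
    if "pause_sites" in data:
        data["pause_sites"] = tuple(
            _build(PauseSite, dict(ps), "ti.pause_sites[]")
            for ps in data["pause_sites"])
    return _build(TIConfig, data, "ti")


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ParameterError(f"{path}: top level must be a mapping")
    unknown = set(raw) - {"ti", "kinetics", "gn", "seed"}
    if unknown:
        raise ParameterError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    if "ti" not in raw:
        raise ParameterError(f"{path}: missing required 'ti' section")
    ti = _build_ti(raw["ti"])
    kin = _build(RNAKinetics, raw["kinetics"], "kinetics") \
        if "kinetics" in raw else None
    gn = _build(GNParams, raw["gn"], "gn") if "gn" in raw else None
    return RunConfig(ti=ti, kinetics=kin, gn=gn, seed=int(raw.get("seed", 0)))


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def config_hash(cfg: RunConfig | TIConfig) -> str:
    """Short stable digest of a configuration (for output headers)."""
    if isinstance(cfg, TIConfig):
        data = dataclasses.asdict(cfg)
    else:
        data = cfg.to_dict()
    blob = json.dumps(data, sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("study-defaults", "noiseless-micro", "symmetric", "randomized")


def make_fixture(name: str, seed: int = 0) -> RunConfig:
    """Named, reproducible parameter bundles used across tests and examples.

    ``study-defaults`` is the main study condition; ``noiseless-micro``
    a ten-round deterministic instance for oracle comparisons; ``symmetric``
    two identical promoters (alpha = 1); ``randomized`` draws promoter and
    geometry parameters from their stated biological ranges under ``seed``.
    """
    if name == "study-defaults":
        return RunConfig(ti=TIConfig.study_defaults(seed=seed),
                         kinetics=RNAKinetics(), gn=GNParams(), seed=seed)
    if name == "noiseless-micro":
        ti = TIConfig(
            pX=PromoterParams("pX", tau_B=20.0, tau_I=12.0, noise_cv=0.0),
            pY=PromoterParams("pY", tau_B=13.7, tau_I=9.5, noise_cv=0.0),
            v_sd=0.0, n_rounds=10, seed=seed,
            sdc_survival=0.0, collision_one_survives=0.0)
        return RunConfig(ti=ti, seed=seed)
    if name == "symmetric":
        ti = TIConfig(
            pX=PromoterParams("pX", tau_B=20.0, tau_I=9.5, noise_cv=0.05),
            pY=PromoterParams("pY", tau_B=20.0, tau_I=9.5, noise_cv=0.05),
            n_rounds=10_000, seed=seed)
        return RunConfig(ti=ti, seed=seed)
    if name == "randomized":
        rng = np.random.default_rng(seed)
        tau_BX = rng.uniform(10.0, 55.0)
        tau_BY = rng.uniform(10.0, 55.0)
        ti = TIConfig(
            pX=PromoterParams("pX", tau_B=tau_BX,
                              tau_I=rng.uniform(5.0, min(9.9, tau_BX - 0.5))),
            pY=PromoterParams("pY", tau_B=tau_BY,
                              tau_I=rng.uniform(5.0, min(9.9, tau_BY - 0.5))),
            L=int(rng.integers(200, 801)),
            n_rounds=2_000, seed=seed)
        return RunConfig(ti=ti, kinetics=RNAKinetics(), seed=seed)
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def _header(lines: dict[str, Any]) -> str:
    out = [f"# convtx {__version__}"]
    out += [f"# {k}: {v}" for k, v in lines.items()]
    return "\n".join(out) + "\n"


def write_tables(results, prefix: str | Path, *, seed: int | None = None) -> list[Path]:
    """Write a result object to TSV/JSON files named ``<prefix>.<what>.<ext>``.

    Dispatches on type: traffic results produce per-round outcome and rate
    tables, sweep DataFrames a single sweep table, bistability scans a branch
    table plus a JSON summary with thresholds and classification.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path, frame: pd.DataFrame, meta: dict) -> None:
        with open(path, "w") as fh:
            fh.write(_header(meta))
            frame.to_csv(fh, sep="\t", index=False)
        written.append(path)

    if isinstance(results, TrafficResult):
        meta = {"config_hash": config_hash(results.config),
                "seed": results.config.seed}
        rows = [{"origin": o.origin, "round": o.round_index, "fate": o.fate,
                 "cause": o.cause,
                 "truncated_length": "" if o.truncated_length is None
                 else o.truncated_length}
                for o in results.outcomes]
        emit(Path(str(prefix) + ".outcomes.tsv"), pd.DataFrame(rows), meta)
        from .traffic import compute_rate_table
        rt = compute_rate_table(results)
        rate_rows = [{"promoter": "pX", "length": "full", "eta": rt.eta_x,
                      "k": rt.k_x},
                     {"promoter": "pY", "length": "full", "eta": rt.eta_y,
                      "k": rt.k_y}]
        rate_rows += [{"promoter": "pX", "length": l, "eta": v,
                       "k": rt.f_X * v} for l, v in sorted(rt.eta_xk.items())]
        rate_rows += [{"promoter": "pY", "length": l, "eta": v,
                       "k": rt.f_Y * v} for l, v in sorted(rt.eta_yh.items())]
        emit(Path(str(prefix) + ".rates.tsv"), pd.DataFrame(rate_rows), meta)
        return written

    if isinstance(results, pd.DataFrame):
        meta = {"seed": seed if seed is not None else "n/a"}
        emit(Path(str(prefix) + ".sweep.tsv"), results, meta)
        return written

    if isinstance(results, BistabilityResult):
        meta = {"seed": seed if seed is not None else "n/a"}
        rows = []
        for branch, states in (("up", results.up_branch),
                               ("down", results.down_branch)):
            for k, st in zip(results.k_WZ_grid, states):
                row = {"k_WZ": k, "branch": branch, "f_Y": st.f_Y,
                       "converged": st.converged}
                row.update({s: getattr(st, s) for s in GN_SPECIES})
                rows.append(row)
        emit(Path(str(prefix) + ".scan.tsv"), pd.DataFrame(rows), meta)
        summary = {"threshold_on": results.threshold_on,
                   "threshold_off": results.threshold_off,
                   "classification": results.classification}
        spath = Path(str(prefix) + ".summary.json")
        spath.write_text(json.dumps(summary, indent=2) + "\n")
        written.append(spath)
        return written

    raise TypeError(f"don't know how to serialise {type(results).__name__}")
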