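"""File interfaces: trial CSV reading, posterior serialization, manifests.

All randomness in a run flows from a single top-level seed; every fit or
simulate invocation writes one JSON run manifest (command, config hash, data
fingerprint, seed, package version, timestamp) so artifacts on disk are
reproducible from (data, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bcf import BCFConfig, BCFPosterior
from .datasets import TrialDataset


@dataclass(frozen=True)
class RunManifest:
    command: str
    config_hash: str
    data_fingerprint: str
    seed: int
    package_version: str
    timestamp: str

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")


def _hash_obj(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def fingerprint_frame(frame: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(frame, index=False).to_numpy().tobytes()
    ).hexdigest()[:16]


def make_manifest(command: str, config: dict, frame: pd.DataFrame, seed: int) -> RunManifest:
    return RunManifest(
        command=command,
        config_hash=_hash_obj(config),
        data_fingerprint=fingerprint_frame(frame),
        seed=int(seed),
        package_version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )


def load_schema(path: str | Path) -> dict:
    """Read a JSON or YAML schema/config file naming the dataset columns."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def read_trial_csv(path: str | Path, schema: dict) -> TrialDataset:
    """Read a long-format trial CSV into a typed :class:`TrialDataset`.

    ``schema`` names the columns: keys ``outcome``, ``arm``, ``unit`` and
    optionally ``time``, ``covariates``, ``moderators``.  Row order is
    preserved; blank cells parse as missing and are flagged, not dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    for key in ("outcome", "arm", "unit"):
        if key not in schema:
            raise ValueError(f"schema is missing the {key!r} column name")
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise ValueError(f"unparseable CSV {path}: {err}") from err
    return TrialDataset(
        frame=frame,
        outcome=schema["outcome"],
        arm=schema["arm"],
        unit=schema["unit"],
        time=schema.get("time"),
        covariates=list(schema.get("covariates", [])),
        moderators=list(schema.get("moderators", [])),
    )


def write_trial_csv(dataset: TrialDataset, path: str | Path) -> None:
    dataset.frame.to_csv(path, index=False)


def write_posterior(posterior: BCFPosterior, out_dir: str | Path) -> dict:
    """Serialize posterior draw matrices as flat CSV tables plus summaries.

    Writes per-block draw tables, a JSON summary file (recomputable from the
    draws), a layout descriptor, and the run manifest.  Refuses to write
    non-finite draws.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blocks = {
        "alpha": posterior.alpha_draws,
        "mu": posterior.mu_draws,
        "sigma": posterior.sigma_draws[:, None],
        "sigma_alpha": posterior.sigma_alpha_draws[:, None],
    }
    for k, tau in posterior.tau_draws.items():
        blocks[f"tau_arm{k}"] = tau
    for name, mat in blocks.items():
        if not np.all(np.isfinite(mat)):
            raise ValueError(f"non-finite values in draw block {name!r}; refusing to write")
    layout = {}
    for name, mat in blocks.items():
        pd.DataFrame(mat).to_csv(out / f"{name}.csv", index=False)
        layout[name] = {"rows": "draws", "cols": int(mat.shape[1])}
    summaries = posterior_summaries(posterior)
    (out / "summaries.json").write_text(json.dumps(summaries, indent=2) + "\n")
    (out / "layout.json").write_text(json.dumps(layout, indent=2) + "\n")
    manifest = make_manifest(
        "write_posterior",
        asdict(posterior.config),
        pd.DataFrame({"row": posterior.row_index}),
        posterior.config.seed,
    )
    manifest.write(out / "manifest.json")
    return summaries


def posterior_summaries(posterior: BCFPosterior) -> dict:
    """ATE summaries per arm, recomputed from the stored draws."""
    from .estimands import summarize_draws

    out = {"arms": {}}
    for k in posterior.arms:
        s = summarize_draws(posterior.ate_draws(k))
        out["arms"][str(k)] = {
            "mean": s.mean,
            "pct_2_5": s.pct_2_5,
            "pct_10": s.pct_10,
            "pct_90": s.pct_90,
            "pct_97_5": s.pct_97_5,
            "prob_direction": s.prob_direction,
            "direction": s.direction,
        }
    out["sigma_mean"] = float(posterior.sigma_draws.mean())
    out["sigma_alpha_mean"] = float(posterior.sigma_alpha_draws.mean())
    return out


def read_posterior_summaries(out_dir: str | Path) -> dict:
    return json.loads((Path(out_dir) / "summaries.json").read_text())
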