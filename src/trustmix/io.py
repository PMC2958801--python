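"""Serialization: dyad CSV tables, severity side tables, chain archives, configs.

Dyad tables are long-format CSV (UTF-8, header, dot decimal) with columns
``dyad_id, group, round, investment_ratio, repayment_ratio``; severity
scores travel in a per-dyad side table ``dyad_id, scale_name,
severity_score``.  Chain archives are JSON: spec, priors, seed, thinning,
and the full recorded draw arrays, written at full float precision so a
round trip is bit-exact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import ModelSpec
from .game_core import DyadRecord, N_ROUNDS, validate_record
from .mixture_gibbs import GibbsChain, PriorSpec

__all__ = [
    "write_dyads_csv",
    "read_dyads_csv",
    "write_severity_csv",
    "read_severity_csv",
    "save_chain",
    "load_chain",
    "write_manifest",
]


def write_dyads_csv(records: Sequence[DyadRecord], path) -> None:
    """Write records as a long-format dyad table (round-trip exact)."""
    rows = []
    for rec in records:
        for t in range(N_ROUNDS):
            rows.append({
                "dyad_id": rec.dyad_id,
                "group": rec.group,
                "round": t + 1,
                "investment_ratio": rec.investments[t],
                "repayment_ratio": rec.repayments[t],
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_dyads_csv(path, severity: Optional[dict] = None,
                   strict: bool = True) -> list:
    """Read a long-format dyad table back into records.

    ``severity`` optionally maps dyad_id -> {scale: score} (see
    :func:`read_severity_csv`).  Malformed rows raise with the offending
    line; with ``strict`` the reconstructed records must also pass
    :func:`trustmix.game_core.validate_record`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"dyad_id", "group", "round",
                "investment_ratio", "repayment_ratio"}
    if not required.issubset(df.columns):
        raise ValueError(f"missing columns: {sorted(required - set(df.columns))}")
    bad = df[~df["round"].between(1, N_ROUNDS)]
    if len(bad):
        raise ValueError(
            f"round outside 1..{N_ROUNDS} at CSV line {bad.index[0] + 2}"
        )
    records = []
    for dyad_id, sub in df.groupby("dyad_id", sort=False):
        sub = sub.sort_values("round")
        if list(sub["round"]) != list(range(1, N_ROUNDS + 1)):
            raise ValueError(f"dyad {dyad_id}: rounds not exactly 1..{N_ROUNDS}")
        group = sub["group"].iloc[0]
        if (sub["group"] != group).any():
            raise ValueError(f"dyad {dyad_id}: inconsistent group labels")
        rec = DyadRecord(
            dyad_id=str(dyad_id), group=str(group),
            investments=sub["investment_ratio"].to_numpy(),
            repayments=sub["repayment_ratio"].to_numpy(),
            severity=(severity or {}).get(str(dyad_id)),
        )
        if strict:
            violations = validate_record(rec)
            if violations:
                raise ValueError(f"dyad {dyad_id}: " + "; ".join(violations))
        records.append(rec)
    return records


def write_severity_csv(records: Sequence[DyadRecord], path) -> None:
    rows = [
        {"dyad_id": rec.dyad_id, "scale_name": scale, "severity_score": score}
        for rec in records if rec.severity
        for scale, score in rec.severity.items()
    ]
    pd.DataFrame(rows, columns=["dyad_id", "scale_name", "severity_score"]) \
        .to_csv(path, index=False, float_format="%.17g")


def read_severity_csv(path) -> dict:
    """Read the severity side table into {dyad_id: {scale: score}}."""
    df = pd.read_csv(path, float_precision="round_trip")
    out: dict = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["dyad_id"]), {})[row["scale_name"]] = \
            float(row["severity_score"])
    return out


def save_chain(chain: GibbsChain, path) -> None:
    """Archive a chain as JSON (full precision, bit-exact round trip)."""
    payload = {
        "spec": {"K": chain.spec.K, "P": chain.spec.P, "D": chain.spec.D},
        "priors": {
            "dirichlet_alpha": chain.priors.dirichlet_alpha.tolist(),
            "beta_mean": chain.priors.beta_mean.tolist(),
            "beta_cov": chain.priors.beta_cov.tolist(),
            "ig_shape": chain.priors.ig_shape,
            "ig_scale": chain.priors.ig_scale,
        },
        "seed": chain.seed,
        "burn_in": chain.burn_in,
        "thin": chain.thin,
        "n_label_switches": chain.n_label_switches,
        "lam": chain.lam.tolist(),
        "beta": chain.beta.tolist(),
        "sigma2": chain.sigma2.tolist(),
        "z": chain.z.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_chain(path) -> GibbsChain:
    d = json.loads(Path(path).read_text())
    return GibbsChain(
        spec=ModelSpec(**d["spec"]),
        priors=PriorSpec(
            dirichlet_alpha=np.asarray(d["priors"]["dirichlet_alpha"]),
            beta_mean=np.asarray(d["priors"]["beta_mean"]),
            beta_cov=np.asarray(d["priors"]["beta_cov"]),
            ig_shape=d["priors"]["ig_shape"],
            ig_scale=d["priors"]["ig_scale"],
        ),
        seed=d["seed"],
        burn_in=d["burn_in"],
        thin=d["thin"],
        n_label_switches=d["n_label_switches"],
        lam=np.asarray(d["lam"], dtype=float),
        beta=np.asarray(d["beta"], dtype=float),
        sigma2=np.asarray(d["sigma2"], dtype=float),
        z=np.asarray(d["z"], dtype=np.int16),
    )


def write_manifest(out_dir, config: dict) -> Path:
    """Write a run manifest: config, its hash, and library versions."""
    import scipy
    import sklearn

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
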