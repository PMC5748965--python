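"""Persistence of wave states: every artifact is traceable to a config hash
and seed, and resuming a persisted match reproduces predictions bit-exactly
on the same platform."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import RunDesign
from .emulator import FittedEmulator
from .history_match import Wave, WaveState
from .implausibility import CutoffPolicy
from .linkage import observations_from_csv, observations_to_csv


class IntegrityError(RuntimeError):
    pass


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def persist_wave(state: WaveState, directory: str | Path, config_hash: str = "") -> None:
    """Write the whole wave state under ``directory`` (one subdir per wave)."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    observations_to_csv(state.observations.values(), root / "observations.csv")
    files: dict[str, str] = {}
    for k, wave in enumerate(state.waves, start=1):
        wdir = root / f"wave{k:02d}"
        (wdir / "emulators").mkdir(parents=True, exist_ok=True)
        wave.design.to_csv(wdir / "design.csv")
        if wave.outputs is not None:
            wave.outputs.to_csv(wdir / "outputs.csv", index=False)
        for name, em in wave.emulators.items():
            em.save_json(wdir / "emulators" / f"{name}.json")
        (wdir / "policy.json").write_text(json.dumps({
            "outputs": list(wave.policy.outputs),
            "c_max": wave.policy.c_max,
            "c_2max": wave.policy.c_2max,
            "c_3max": wave.policy.c_3max,
            "seed": wave.seed,
            "n_failed": wave.n_failed,
        }, indent=1))
        for f in sorted(wdir.rglob("*")):
            if f.is_file():
                files[str(f.relative_to(root))] = _sha(f)
    (root / "volume.json").write_text(json.dumps({
        "volume_history": state.volume_history,
        "status": state.status,
    }, indent=1))
    meta = {
        "config_hash": config_hash,
        "names": list(state.names),
        "ranges": state.ranges.tolist(),
        "provenance": state.provenance,
        "n_waves": len(state.waves),
        "files": files,
        "cache": None if state.nonimplausible_cache is None
        else state.nonimplausible_cache.tolist(),
    }
    (root / "manifest.json").write_text(json.dumps(meta))


def resume_wave(directory: str | Path, config_hash: str = "") -> WaveState:
    """Reload a persisted wave state, verifying config hash and file hashes."""
    root = Path(directory)
    meta = json.loads((root / "manifest.json").read_text())
    if config_hash and meta["config_hash"] and meta["config_hash"] != config_hash:
        raise IntegrityError(
            f"config hash mismatch: stored {meta['config_hash']}, current {config_hash}"
        )
    for rel, digest in meta["files"].items():
        f = root / rel
        if not f.exists() or _sha(f) != digest:
            raise IntegrityError(f"stored artifact {rel} is missing or was modified")

    observations = observations_from_csv(root / "observations.csv")
    vol = json.loads((root / "volume.json").read_text())
    state = WaveState(
        ranges=np.asarray(meta["ranges"], float),
        names=tuple(meta["names"]),
        observations=observations,
        volume_history=[tuple(v) for v in vol["volume_history"]],
        status=vol["status"],
        provenance=meta["provenance"],
        nonimplausible_cache=None if meta["cache"] is None
        else np.asarray(meta["cache"], float),
    )
    for k in range(1, meta["n_waves"] + 1):
        wdir = root / f"wave{k:02d}"
        design = RunDesign.from_csv(wdir / "design.csv")
        pol = json.loads((wdir / "policy.json").read_text())
        outputs = (
            pd.read_csv(wdir / "outputs.csv") if (wdir / "outputs.csv").exists() else None
        )
        emulators = {
            f.stem: FittedEmulator.load_json(f)
            for f in sorted((wdir / "emulators").glob("*.json"))
        }
        state.waves.append(Wave(
            design=design, outputs=outputs, emulators=emulators,
            policy=CutoffPolicy(outputs=tuple(pol["outputs"]), c_max=pol["c_max"],
                                c_2max=pol["c_2max"], c_3max=pol["c_3max"]),
            diagnostics={}, seed=pol["seed"], n_failed=pol["n_failed"],
        ))
    return state
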