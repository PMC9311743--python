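"""File outputs: per-replicate summary/sample CSVs and reproducibility
manifests (RFC-4180 CSV, UTF-8, '.' decimal separator; JSON manifests)."""
from __future__ import annotations

import json
from pathlib import Path

from ._version import __version__
from .scenarios import SweepResult
from .simulate import RunResult, SAMPLE_COLUMNS, SUMMARY_COLUMNS


def replicate_manifest(result: RunResult, paths: dict[str, str],
                       replicate: int = 0) -> dict:
    """Everything needed to re-execute one replicate bit for bit: the full
    parameter snapshot, the replicate seed, its status and output paths."""
    return {
        "version": __version__,
        "replicate": replicate,
        "seed": result.seed,
        "status": result.status,
        "turns_completed": result.turns_completed,
        "params": result.params.to_dict(),
        "outputs": paths,
    }


def write_outputs(result: RunResult, out_dir: str | Path,
                  label: str = "run", replicate: int = 0) -> dict[str, str]:
    """Write one replicate's summary CSV, chromosome-sample CSV (coexisting
    runs only) and manifest JSON; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{label}_rep{replicate}"
    paths: dict[str, str] = {}

    summary_path = out_dir / f"{stem}_summary.csv"
    result.summary.to_csv(summary_path, index=False, columns=SUMMARY_COLUMNS)
    paths["summary"] = str(summary_path)

    if result.completed and result.samples is not None:
        samples = result.samples.copy()
        samples.insert(0, "seed", result.seed)
        samples.insert(0, "replicate", replicate)
        samples_path = out_dir / f"{stem}_samples.csv"
        samples.to_csv(samples_path, index=False,
                       columns=["replicate", "seed"] + SAMPLE_COLUMNS)
        paths["samples"] = str(samples_path)

    manifest_path = out_dir / f"{stem}_manifest.json"
    manifest_path.write_text(
        json.dumps(replicate_manifest(result, paths, replicate), indent=2))
    paths["manifest"] = str(manifest_path)
    return paths


def sweep_manifest(sweeps: list[SweepResult], base_seed: int) -> dict:
    """Machine-readable sweep record: every replicate's seed and status per
    condition, sufficient for exact re-execution."""
    return {
        "version": __version__,
        "base_seed": base_seed,
        "conditions": [
            {
                "index": i,
                "label": sw.condition.label,
                "params": sw.condition.params.to_dict(),
                "replicates": [
                    {"replicate": r, "seed": seed, "status": res.status}
                    for r, (seed, res) in enumerate(zip(sw.seeds, sw.results))
                ],
            }
            for i, sw in enumerate(sweeps)
        ],
    }


def write_sweep(sweeps: list[SweepResult], out_dir: str | Path,
                base_seed: int) -> dict[str, str]:
    """Write every replicate of a sweep plus the sweep-level manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for sw in sweeps:
        for r, res in enumerate(sw.results):
            rep_paths = write_outputs(res, out_dir, label=sw.condition.label,
                                      replicate=r)
            paths.update({f"{sw.condition.label}_rep{r}_{k}": v
                          for k, v in rep_paths.items()})
    manifest_path = Path(out_dir) / "sweep_manifest.json"
    manifest_path.write_text(json.dumps(sweep_manifest(sweeps, base_seed),
                                        indent=2))
    paths["sweep_manifest"] = str(manifest_path)
    return paths
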