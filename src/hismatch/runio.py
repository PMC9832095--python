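"""Run-directory persistence: diffable CSV + JSON artifacts, no binaries.

Layout written by :func:`save_run` / read by :func:`load_run`::

    config.json          run configuration (WaveConfig fields)
    space.json           parameter-space definition
    targets.json         calibration targets (mu, sigma per biomarker)
    ledger.csv           every simulation consumed: natural-frame x + biomarkers
    reference_set.csv    fixed Sobol' set used for all NROY-size estimates
    wave<k>_bank.json    emulator hyperparameters for wave k
    wave<k>_bank_train.csv  the bank's training matrices
    report.json          per-wave NROY %, VQ, scores, I(truth)

Candidate sets are not persisted: NROY membership is recomputed from the
banks and thresholds, which is exact and keeps run directories small.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gp import EmulatorBank
from .history_matching import (
    HistoryMatchingResults,
    TargetSpec,
    WaveConfig,
    WaveState,
)
from .parameter_space import ParameterSpace

__all__ = ["save_run", "load_run", "write_report_tables"]


def save_run(results: HistoryMatchingResults, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "config.json").write_text(
        json.dumps(results.config.to_dict(), indent=2)
    )
    (directory / "space.json").write_text(results.space.to_json())
    (directory / "targets.json").write_text(
        json.dumps(results.targets.to_dict(), indent=2)
    )
    results.ledger.to_csv(directory / "ledger.csv", index=False)
    pd.DataFrame(results.reference_set, columns=list(results.space.names)).to_csv(
        directory / "reference_set.csv", index=False
    )
    for ws in results.waves:
        ws.bank.save(directory, f"wave{ws.wave_index}_bank")
    report = {
        "truth": None if results.truth is None else results.truth.tolist(),
        "n_simulations": results.n_simulations,
        "waves": results.wave_report().to_dict(orient="records"),
        "per_biomarker_scores": {
            str(ws.wave_index): ws.scores for ws in results.waves
        },
    }
    (directory / "report.json").write_text(json.dumps(report, indent=2))


def load_run(directory) -> HistoryMatchingResults:
    """Rebuild a results object from a run directory.

    Candidate sets are not restored (they are fit-time scaffolding); all
    NROY statistics recompute exactly from the persisted banks.
    """
    directory = Path(directory)
    config = WaveConfig.from_dict(json.loads((directory / "config.json").read_text()))
    space = ParameterSpace.from_json((directory / "space.json").read_text())
    targets = TargetSpec.from_dict(json.loads((directory / "targets.json").read_text()))
    ledger = pd.read_csv(directory / "ledger.csv")
    reference = pd.read_csv(directory / "reference_set.csv").to_numpy(dtype=float)
    # reference_set.csv stores unit-frame points under parameter-name headers
    report = json.loads((directory / "report.json").read_text())
    waves = []
    for k, threshold in enumerate(config.thresholds, start=1):
        bank_path = directory / f"wave{k}_bank.json"
        if not bank_path.exists():
            raise FileNotFoundError(
                f"run directory {directory} has no bank for wave {k} "
                f"(expected {bank_path.name})"
            )
        bank = EmulatorBank.load(directory, f"wave{k}_bank")
        waves.append(WaveState(
            wave_index=k, bank=bank, threshold=threshold,
            candidates=None, implausibility=None, nroy_mask=None,
            scores=report.get("per_biomarker_scores", {}).get(str(k), {}),
        ))
    truth = report.get("truth")
    return HistoryMatchingResults(
        space=space, targets=targets, config=config, waves=waves,
        reference_set=reference, ledger=ledger,
        truth=None if truth is None else np.asarray(truth, dtype=float),
    )


def write_report_tables(results: HistoryMatchingResults, directory,
                        n_bins: int = 20) -> None:
    """Regenerate the CSV report tables for a (possibly reloaded) run."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    results.wave_report().to_csv(directory / "wave_summary.csv", index=False)
    results.frequency_map(n_bins=n_bins).to_csv(
        directory / "frequency_map.csv", index=False
    )
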