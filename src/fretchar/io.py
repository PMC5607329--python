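"""File dialects: two-column spectrum CSVs, TIFF phase stacks with YAML
sidecars, and trace CSVs with manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .flim import PhaseStack
from .spectra import Spectrum
from .traces import IntensityTrace

__all__ = [
    "write_spectrum",
    "write_phase_stack",
    "read_phase_stack",
    "write_trace",
    "read_trace",
]


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    """Write a spectrum as a wavelength_nm,value CSV with a header row."""
    pd.DataFrame(
        {"wavelength_nm": spec.wavelengths_nm, "value": spec.values}
    ).to_csv(path, index=False)


def write_phase_stack(stack: PhaseStack, path: str | Path) -> None:
    """Write frames as a multi-page 32-bit TIFF plus a YAML sidecar with the
    phase steps, modulation frequency and acquisition order."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    meta = {
        "phase_steps_rad": [float(x) for x in stack.phase_steps_rad],
        "modulation_frequency_hz": float(stack.modulation_frequency_hz),
        "acquisition_order": (
            [int(i) for i in stack.acquisition_order]
            if stack.acquisition_order is not None
            else None
        ),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def read_phase_stack(path: str | Path) -> PhaseStack:
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=float)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    return PhaseStack(
        frames=frames,
        phase_steps_rad=np.asarray(meta["phase_steps_rad"], dtype=float),
        modulation_frequency_hz=float(meta["modulation_frequency_hz"]),
        acquisition_order=(
            np.asarray(meta["acquisition_order"])
            if meta.get("acquisition_order") is not None
            else None
        ),
    )


def write_trace(trace: IntensityTrace, path: str | Path) -> None:
    """Trace CSV (time_s, donor, acceptor) + JSON manifest with backgrounds
    and event times."""
    path = Path(path)
    pd.DataFrame(
        {"time_s": trace.time_s, "donor": trace.donor, "acceptor": trace.acceptor}
    ).to_csv(path, index=False)
    manifest = {
        "background_donor": float(np.mean(trace.background_donor)),
        "background_acceptor": float(np.mean(trace.background_acceptor)),
        "agonist_s": trace.agonist_s,
        "antagonist_s": trace.antagonist_s,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def read_trace(path: str | Path) -> IntensityTrace:
    path = Path(path)
    df = pd.read_csv(path)
    manifest_path = path.with_suffix(".json")
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    return IntensityTrace(
        time_s=df["time_s"].to_numpy(),
        donor=df["donor"].to_numpy(),
        acceptor=df["acceptor"].to_numpy(),
        background_donor=manifest.get("background_donor", 0.0),
        background_acceptor=manifest.get("background_acceptor", 0.0),
        agonist_s=manifest.get("agonist_s"),
        antagonist_s=manifest.get("antagonist_s"),
    )
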