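"""Columnar trajectory container with TSV round-trip."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

__all__ = ["TrajectoryStore"]


class TrajectoryStore:
    """Time series of CV samples and recorded observables.

    A thin wrapper around a :class:`pandas.DataFrame` with documented columns:

    ``step``          integer MD step index
    ``time``          step * timestep
    ``Q``             collective-variable value
    ``U``             potential energy (with any Hamiltonian scaling applied)
    ``bias_energy``   bias potential V(Q) at the sampling weights then in force
    ``log_denom``     log of the force-mixture denominator integral
                      log \\int dF' omega(F') e^{beta F' Q} (FISST runs only);
                      together with Q this is sufficient to recompute every
                      per-frame observable weight W_F after the fact
    plus one column per recorded observable.

    ``meta`` carries run provenance (beta, timestep, scheme, seed, ...).
    """

    def __init__(self, frame: pd.DataFrame, meta: dict | None = None) -> None:
        self.frame = frame
        self.meta = dict(meta or {})

    def __len__(self) -> int:
        return len(self.frame)

    def __getitem__(self, col: str) -> np.ndarray:
        return self.frame[col].to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def beta(self) -> float:
        return float(self.meta["beta"])

    def head(self, n: int) -> "TrajectoryStore":
        """Prefix of the first n frames (used by convergence analyses)."""
        return TrajectoryStore(self.frame.iloc[:n].reset_index(drop=True), self.meta)

    # -- I/O --------------------------------------------------------------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# fisstkit-trajectory\t" + json.dumps(self.meta, sort_keys=True) + "\n")
            self.frame.to_csv(fh, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "TrajectoryStore":
        with open(path) as fh:
            header = fh.readline()
            meta = {}
            if header.startswith("# fisstkit-trajectory"):
                meta = json.loads(header.split("\t", 1)[1])
            else:
                fh.seek(0)
            frame = pd.read_csv(fh, sep="\t", float_precision="round_trip")
        return cls(frame, meta)
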