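"""Reading and writing collective-variable trajectories and window configs.

The trajectory dialect is a plain-text whitespace table in the style of the
NAMD colvars trajectory output: lines starting with ``#`` are comments, the
last ``#`` line before the first data row names the columns, the first
column is the integration step, and the remaining columns are collective
variables (CVs).  Window/bias configurations are YAML.

Angles are stored in radians internally; CVs and force constants declared in
degrees are converted at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .constants import DEG2_TO_RAD2


class CVFormatError(ValueError):
    """Malformed trajectory or configuration input."""


@dataclass
class CVTrajectory:
    """Per-window time series of collective variables.

    Parameters
    ----------
    window_id : str
        Identifier of the sampling window this trajectory came from.
    steps : ndarray of int
        Strictly increasing frame step numbers.
    values : pandas.DataFrame
        One row per frame, one column per CV.  Distances and RMSDs in Å,
        angles in radians.
    """

    window_id: str
    steps: np.ndarray
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps)
        if len(self.steps) != len(self.values):
            raise CVFormatError("steps and values must have the same length")
        if len(self.steps) > 1 and not np.all(np.diff(self.steps) > 0):
            raise CVFormatError(
                f"steps must be strictly increasing in window {self.window_id!r}"
            )
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise CVFormatError(
                f"non-finite CV value in window {self.window_id!r}"
            )

    @property
    def cvs(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class BiasSpec:
    """One harmonic bias U(v) = 1/2 k (v - center)^2 on a named CV.

    ``center`` is in the CV's internal unit (Å or radians) and
    ``force_constant`` in kcal/mol per unit^2.
    """

    cv: str
    center: float
    force_constant: float
    kind: str = "harmonic"

    def __post_init__(self) -> None:
        if self.kind != "harmonic":
            raise CVFormatError(f"unsupported bias kind {self.kind!r}")
        if self.force_constant < 0:
            raise CVFormatError(
                f"negative force constant {self.force_constant} on CV {self.cv!r}"
            )

    def energy(self, value: np.ndarray | float) -> np.ndarray | float:
        return 0.5 * self.force_constant * (np.asarray(value) - self.center) ** 2


@dataclass
class WindowConfig:
    """Ordered set of umbrella windows, each with its list of biases."""

    windows: list[tuple[str, list[BiasSpec]]]
    temperature: float
    declared_cvs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.windows:
            raise CVFormatError("window list is empty")
        if self.temperature <= 0:
            raise CVFormatError(f"temperature must be positive, got {self.temperature}")
        if self.declared_cvs:
            known = set(self.declared_cvs)
            for wid, biases in self.windows:
                for b in biases:
                    if b.cv not in known:
                        raise CVFormatError(
                            f"window {wid!r} biases unknown CV {b.cv!r}"
                        )

    @property
    def window_ids(self) -> list[str]:
        return [wid for wid, _ in self.windows]

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def biases_for(self, window_id: str) -> list[BiasSpec]:
        for wid, biases in self.windows:
            if wid == window_id:
                return biases
        raise KeyError(window_id)


def read_cv_trajectory(
    path: str | Path,
    declared_cvs: Sequence[str],
    window_id: str | None = None,
    degree_cvs: Iterable[str] = (),
) -> CVTrajectory:
    """Parse a colvars-style trajectory file.

    ``declared_cvs`` are the CV columns that must be present (besides the
    leading ``step`` column).  CVs listed in ``degree_cvs`` are converted
    from degrees to radians on read.
    """
    path = Path(path)
    header: list[str] | None = None
    steps: list[int] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                if not rows:  # last header line before data wins
                    tokens = stripped.lstrip("#").split()
                    if tokens:
                        header = tokens
                continue
            tokens = stripped.split()
            try:
                values = [float(t) for t in tokens]
            except ValueError as exc:
                raise CVFormatError(
                    f"{path.name}:{lineno}: non-numeric token in data row: {exc}"
                ) from None
            if header is not None and len(values) != len(header):
                raise CVFormatError(
                    f"{path.name}:{lineno}: expected {len(header)} columns, "
                    f"got {len(values)}"
                )
            steps.append(int(values[0]))
            rows.append(values[1:])
    if header is None:
        raise CVFormatError(f"{path.name}: no '#' header line naming the columns")
    columns = header[1:]
    missing = [cv for cv in declared_cvs if cv not in columns]
    if missing:
        raise CVFormatError(
            f"{path.name}: declared CV column(s) missing: {', '.join(missing)}"
        )
    frame = pd.DataFrame(rows, columns=columns)[list(declared_cvs)]
    for cv in degree_cvs:
        if cv in frame.columns:
            frame[cv] = np.deg2rad(frame[cv])
    return CVTrajectory(
        window_id=window_id or path.stem,
        steps=np.asarray(steps, dtype=np.int64),
        values=frame,
    )


def write_cv_trajectory(traj: CVTrajectory, path: str | Path) -> None:
    """Write a trajectory in the same dialect (full float precision)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# step " + " ".join(traj.cvs) + "\n")
        arr = traj.values.to_numpy(dtype=float)
        for step, row in zip(traj.steps, arr):
            fh.write(str(int(step)) + " " + " ".join(f"{v:.17g}" for v in row) + "\n")


def _parse_bias(entry: dict, window_id: str) -> BiasSpec:
    try:
        cv = entry["cv"]
        center = float(entry["center"])
        k = float(entry["k"])
    except (KeyError, TypeError, ValueError) as exc:
        raise CVFormatError(f"window {window_id!r}: bad bias entry {entry!r}: {exc}")
    unit = entry.get("unit", "internal")
    if unit in ("degree", "deg"):
        center = float(np.deg2rad(center))
        k = k * DEG2_TO_RAD2
    elif unit not in ("internal", "angstrom", "A", "radian", "rad"):
        raise CVFormatError(f"window {window_id!r}: unknown unit {unit!r}")
    return BiasSpec(cv=cv, center=center, force_constant=k)


def read_window_config(path: str | Path) -> WindowConfig:
    """Read a YAML window/bias configuration.

    Expected layout::

        temperature: 300.0
        cvs: [d, omega]        # optional declaration used for validation
        windows:
          - id: w00
            biases:
              - {cv: d, center: 10.0, k: 2.0, unit: angstrom}
              - {cv: omega, center: 0.0, k: 0.5, unit: degree}
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise CVFormatError(f"{path.name}: top level must be a mapping")
    try:
        temperature = float(doc["temperature"])
    except (KeyError, TypeError, ValueError):
        raise CVFormatError(f"{path.name}: missing or bad 'temperature'")
    raw_windows = doc.get("windows") or []
    windows = []
    for i, w in enumerate(raw_windows):
        wid = str(w.get("id", f"w{i:02d}"))
        biases = [_parse_bias(b, wid) for b in w.get("biases", [])]
        windows.append((wid, biases))
    return WindowConfig(
        windows=windows,
        temperature=temperature,
        declared_cvs=list(doc.get("cvs", [])),
    )


def write_window_config(config: WindowConfig, path: str | Path) -> None:
    """Write a WindowConfig as YAML (internal units: Å / radians)."""
    doc = {
        "temperature": float(config.temperature),
        "cvs": list(config.declared_cvs),
        "windows": [
            {
                "id": wid,
                "biases": [
                    {
                        "cv": b.cv,
                        "center": float(b.center),
                        "k": float(b.force_constant),
                        "unit": "internal",
                    }
                    for b in biases
                ],
            }
            for wid, biases in config.windows
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
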