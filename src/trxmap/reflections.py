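"""Reflection-list handling: I/O, scaling, reference averaging, differences.

A :class:`ReflectionSet` is a thin wrapper over a pandas DataFrame keyed by
Miller indices, carrying structure-factor amplitudes and, for calculated
sets, phases.  Observed sets are put on the scale of a calculated set with a
Wilson-style fit (linear scale ``k`` plus a relative overall B factor), after
which per-delay difference amplitudes ``d|F| = |F(t)| - |F(ref)|`` feed the
difference-Fourier map synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._cell import s_of_hkl

__all__ = [
    "ReflectionSet",
    "DifferenceSet",
    "ScaleResult",
    "read_hkl",
    "write_hkl",
    "scale_to_calc",
    "reference_amplitudes",
    "difference_amplitudes",
]

_KEY = ["h", "k", "l"]


@dataclass
class ReflectionSet:
    """Indexed structure-factor amplitudes on a unit cell.

    ``data`` columns: h, k, l (int), F (amplitude, electrons), optionally
    sigF and phase (radians).  Keys are unique.
    """

    cell: tuple[float, float, float, float, float, float]
    data: pd.DataFrame
    label: str = ""

    def __post_init__(self):
        df = self.data.reset_index(drop=True)
        for c in _KEY:
            df[c] = df[c].astype(int)
        if df.duplicated(_KEY).any():
            dup = df[df.duplicated(_KEY)].iloc[0]
            raise ValueError(
                f"duplicate reflection ({dup.h} {dup.k} {dup.l}) in {self.label!r}"
            )
        if len(df) and (df["F"] < 0).any():
            raise ValueError("amplitudes must be non-negative")
        self.data = df

    # -- construction ------------------------------------------------------

    @classmethod
    def from_arrays(cls, cell, hkl, amplitude, sigma=None, phase=None, label=""):
        hkl = np.asarray(hkl, int)
        df = pd.DataFrame(
            {"h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2],
             "F": np.asarray(amplitude, float)}
        )
        if sigma is not None:
            df["sigF"] = np.asarray(sigma, float)
        if phase is not None:
            df["phase"] = np.asarray(phase, float)
        return cls(tuple(cell), df, label)

    def with_amplitudes(self, amplitude, phase="keep", label=None):
        """Copy with replaced amplitudes; ``phase=None`` drops phases."""
        df = self.data.copy()
        df["F"] = np.asarray(amplitude, float)
        if phase is None and "phase" in df:
            df = df.drop(columns="phase")
        elif phase is not None and not isinstance(phase, str):
            df["phase"] = np.asarray(phase, float)
        return ReflectionSet(self.cell, df, label if label is not None else self.label)

    # -- accessors ---------------------------------------------------------

    @property
    def has_phases(self) -> bool:
        return "phase" in self.data.columns

    def __len__(self) -> int:
        return len(self.data)

    @property
    def hkl(self) -> np.ndarray:
        return self.data[_KEY].to_numpy()

    @property
    def amplitude(self) -> np.ndarray:
        return self.data["F"].to_numpy()

    @property
    def phase(self) -> np.ndarray:
        if not self.has_phases:
            raise ValueError(f"reflection set {self.label!r} carries no phases")
        return self.data["phase"].to_numpy()

    def complex_f(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)

    def s_array(self) -> np.ndarray:
        """s = 1/d (Å^-1) for every reflection."""
        return s_of_hkl(self.cell, self.hkl)

    def resolution_of(self, h: int, k: int, l: int) -> float:
        """d-spacing (Å) of one reflection; inf for (0,0,0)."""
        s = float(s_of_hkl(self.cell, np.array([[h, k, l]]))[0])
        return np.inf if s == 0 else 1.0 / s


@dataclass
class DifferenceSet:
    """Signed difference amplitudes d|F| on the parent sets' intersection."""

    cell: tuple
    data: pd.DataFrame  # columns h, k, l, dF
    reference_label: str = ""

    @property
    def hkl(self) -> np.ndarray:
        return self.data[_KEY].to_numpy()

    @property
    def delta(self) -> np.ndarray:
        return self.data["dF"].to_numpy()

    def scaled(self, factor: float) -> "DifferenceSet":
        df = self.data.copy()
        df["dF"] = df["dF"] * factor
        return DifferenceSet(self.cell, df, self.reference_label)


@dataclass
class ScaleResult:
    """Wilson-fit scale between an observed and a calculated set.

    Model: ``ln <|F_obs|^2 / |F_calc|^2>_bin = ln k - dB s^2 / 2``; the
    corrected observed amplitudes are ``|F_obs| k^(-1/2) exp(+dB s^2/4)``.
    """

    k: float
    delta_b: float
    per_bin: pd.DataFrame  # columns s2_center, log_ratio, n

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("scale factor k must be positive")


# ---------------------------------------------------------------------------
# I/O


def write_hkl(refl: ReflectionSet, path, dialect: str = "shelx-f") -> None:
    """Write a reflection list as SHELX-style fixed width or TSV."""
    path = Path(path)
    if dialect == "shelx-f":
        with open(path, "w") as fh:
            for row in refl.data.itertuples(index=False):
                sig = getattr(row, "sigF", 0.0)
                if pd.isna(sig):
                    sig = 0.0
                fh.write(f"{row.h:4d}{row.k:4d}{row.l:4d}{row.F:8.2f}{sig:8.2f}\n")
    elif dialect == "tsv":
        df = refl.data.copy()
        if "phase" in df:
            df["phase_deg"] = np.degrees(df.pop("phase"))
        with open(path, "w") as fh:
            fh.write("# cell " + " ".join(f"{x:g}" for x in refl.cell) + "\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.8g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_hkl(path, dialect: str = "shelx-f", cell=(1, 1, 1, 90, 90, 90)) -> ReflectionSet:
    """Read a reflection list; raises on malformed lines or duplicate keys."""
    path = Path(path)
    if dialect == "shelx-f":
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise ValueError(
                        f"{path.name}: malformed reflection line {ln}: {line!r}"
                    )
                try:
                    h, k, l = (int(p) for p in parts[:3])
                    f = float(parts[3])
                    sig = float(parts[4]) if len(parts) > 4 else 0.0
                except ValueError as exc:
                    raise ValueError(
                        f"{path.name}: malformed reflection line {ln}: {line!r}"
                    ) from exc
                rows.append((h, k, l, f, sig))
        df = pd.DataFrame(rows, columns=["h", "k", "l", "F", "sigF"])
    elif dialect == "tsv":
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("# cell"):
            cell = tuple(float(x) for x in first.split()[2:8])
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = [c for c in ("h", "k", "l", "F") if c not in df.columns]
        if missing:
            raise ValueError(f"{path.name}: missing columns {missing}")
        if "phase_deg" in df:
            df["phase"] = np.radians(df.pop("phase_deg"))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return ReflectionSet(tuple(cell), df, label=path.stem)


# ---------------------------------------------------------------------------
# Scaling and differences


def _merged(a: ReflectionSet, b: ReflectionSet, suffixes=("_a", "_b")) -> pd.DataFrame:
    m = a.data.merge(b.data, on=_KEY, suffixes=suffixes)
    if m.empty:
        raise ValueError(
            f"reflection sets {a.label!r} and {b.label!r} share no indices"
        )
    return m


def scale_to_calc(
    obs: ReflectionSet,
    calc: ReflectionSet,
    nbins: int = 10,
    use_intensities: bool = True,
    apply_b: bool = True,
) -> tuple[ScaleResult, ReflectionSet]:
    """Wilson-style scaling of observed amplitudes onto a calculated set.

    Bins common reflections in s^2, fits ``ln <ratio> = ln k - dB s^2/2``
    by least squares over the bin means (ratio of squared amplitudes by
    default, plain amplitude ratio with ``use_intensities=False``), and
    returns both the fit and the corrected observed set.

    With ``apply_b=False`` only the linear scale ``k`` is applied to the
    returned amplitudes; the fitted ``dB`` is still reported.  This is the
    right choice when a genuine overall-B change between datasets (for
    example vibrational heating) is itself the signal of interest — applying
    the exp(+dB s^2/4) correction would subtract it.
    """
    m = _merged(obs, calc, ("_obs", "_calc"))
    s2 = s_of_hkl(obs.cell, m[_KEY].to_numpy()) ** 2
    good = (m["F_obs"].to_numpy() > 0) & (m["F_calc"].to_numpy() > 0)
    ratio = np.where(
        good, m["F_obs"].to_numpy() ** 2 / np.where(good, m["F_calc"].to_numpy(), 1) ** 2, np.nan
    )
    if not use_intensities:
        ratio = np.sqrt(ratio)

    edges = np.linspace(s2[good].min(), s2[good].max() * (1 + 1e-9), nbins + 1)
    idx = np.digitize(s2, edges) - 1
    centers, logs, counts = [], [], []
    for b in range(nbins):
        sel = good & (idx == b)
        if sel.sum() >= 3:
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            logs.append(float(np.log(np.nanmean(ratio[sel]))))
            counts.append(int(sel.sum()))
    if len(centers) < 2:
        raise ValueError(
            "need at least 2 resolution bins with >= 3 common reflections"
        )
    centers = np.array(centers)
    logs = np.array(logs)
    slope, intercept = np.polyfit(centers, logs, 1)
    if not use_intensities:
        # |F| ratio model: ln<|Fo|/|Fc|> = ln sqrt(k) - dB s^2/4
        intercept *= 2.0
        slope *= 2.0
    k = float(np.exp(intercept))
    delta_b = float(-2.0 * slope)

    s_all = obs.s_array()
    corr = obs.amplitude * k**-0.5
    if apply_b:
        corr = corr * np.exp(+delta_b * s_all**2 / 4.0)
    scaled = obs.with_amplitudes(corr, label=f"{obs.label}|scaled")
    per_bin = pd.DataFrame(
        {"s2_center": centers, "log_ratio": logs, "n": counts}
    )
    return ScaleResult(k, delta_b, per_bin), scaled


def reference_amplitudes(
    series: dict[float, ReflectionSet], grid
) -> ReflectionSet:
    """Average amplitudes over the negative-delay reference subset.

    Strict intersection: a reflection missing from any reference delay is
    dropped.  Raises if a reference delay is absent from ``series``.
    """
    refs = []
    for t in grid.negative_reference:
        if t not in series:
            raise ValueError(f"reference delay {t} ps missing from the series")
        refs.append(series[t])
    merged = refs[0].data[_KEY + ["F"]].rename(columns={"F": "F0"})
    for i, r in enumerate(refs[1:], start=1):
        merged = merged.merge(
            r.data[_KEY + ["F"]].rename(columns={"F": f"F{i}"}), on=_KEY
        )
    if merged.empty:
        raise ValueError("reference delays share no reflections")
    fcols = [c for c in merged.columns if c.startswith("F")]
    out = merged[_KEY].copy()
    out["F"] = merged[fcols].mean(axis=1)
    return ReflectionSet(refs[0].cell, out, label="reference")


def difference_amplitudes(set_t: ReflectionSet, ref: ReflectionSet) -> DifferenceSet:
    """d|F| = |F(t)| - |F(ref)| on the index intersection."""
    m = _merged(set_t, ref, ("_t", "_ref"))
    df = m[_KEY].copy()
    df["dF"] = m["F_t"] - m["F_ref"]
    return DifferenceSet(set_t.cell, df, reference_label=ref.label)
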