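"""Wavelength-resolved optical properties per tissue.

Each tissue carries four properties: the absorption coefficient mu_a and
scattering coefficient mu_s (both mm^-1), the Henyey-Greenstein anisotropy
g (mean cosine of the scattering angle, -1 < g < 1) and the refractive
index n.  A table stores these on a shared wavelength grid (the default
table spans 400-1100 nm in 10 nm steps) and interpolates linearly in
between.  Ambient medium (tissue ID 0) is non-interacting with n = 1.

The shipped default table is a literature-style parametric reconstruction:
per-tissue volume fractions of blood, water and melanin mixed over anchor
chromophore spectra, plus a power-law reduced-scattering term
mu_s'(lambda) = a (lambda/500 nm)^-b converted with a per-tissue g.  It is
a replaceable default, not a measurement; disease states are expressed as
named override sets applied on top of any table.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OpticalProperties",
    "OpticalSpectraTable",
    "default_spectra",
    "uniform_spectra",
    "load_spectra",
    "save_spectra",
    "ARTHRITIC_OVERRIDES",
]

_FIELDS = ("mu_a", "mu_s", "g", "n")


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of one tissue at one wavelength."""

    mu_a: float  # absorption coefficient, mm^-1
    mu_s: float  # scattering coefficient, mm^-1
    g: float  # scattering anisotropy, dimensionless
    n: float  # refractive index

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if not (-1.0 < self.g < 1.0):
            raise ValueError("anisotropy g must lie strictly in (-1, 1)")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def mu_t(self) -> float:
        return self.mu_a + self.mu_s


AMBIENT_PROPERTIES = OpticalProperties(0.0, 0.0, 0.0, 1.0)


class OpticalSpectraTable:
    """Per-tissue optical-property spectra on a shared wavelength grid.

    Internally one ``(4, n_wavelengths)`` float array per tissue ID, in the
    field order (mu_a, mu_s, g, n), units mm^-1 for the coefficients.
    """

    def __init__(self, wavelengths: np.ndarray, rows: dict[int, np.ndarray]):
        wl = np.asarray(wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 1:
            raise ValueError("wavelength grid must be a 1D array")
        if np.unique(wl).size != wl.size:
            dup = wl[np.concatenate(([False], np.diff(np.sort(wl)) == 0))]
            raise ValueError(f"duplicate wavelengths in grid: {np.unique(dup)}")
        order = np.argsort(wl)
        self.wavelengths = wl[order]
        self.rows: dict[int, np.ndarray] = {}
        for tid, arr in rows.items():
            a = np.asarray(arr, dtype=float)
            if a.shape != (4, wl.size):
                raise ValueError(
                    f"tissue {tid}: expected shape (4, {wl.size}), got {a.shape}"
                )
            self.rows[int(tid)] = a[:, order].copy()
        self._validate()

    def _validate(self) -> None:
        for tid, a in self.rows.items():
            mu_a, mu_s, g, n = a
            if np.any(~np.isfinite(a)):
                raise ValueError(f"tissue {tid}: non-finite property value")
            if np.any(mu_a < 0) or np.any(mu_s < 0):
                raise ValueError(f"tissue {tid}: negative mu_a or mu_s")
            if np.any((g <= -1.0) | (g >= 1.0)):
                raise ValueError(f"tissue {tid}: anisotropy g outside (-1, 1)")
            if np.any(n < 1.0):
                raise ValueError(f"tissue {tid}: refractive index below 1")

    @property
    def tissue_ids(self) -> list[int]:
        return sorted(self.rows)

    @property
    def wavelength_range(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def require_rows(self, tissue_ids) -> None:
        missing = sorted(set(int(t) for t in tissue_ids) - {0} - set(self.rows))
        if missing:
            raise KeyError(f"no optical-property rows for tissue IDs {missing}")

    def properties_at(self, tissue_id: int, wavelength: float) -> OpticalProperties:
        """Properties of one tissue at one wavelength (nm).

        Exact stored values on grid points, linear interpolation between;
        ambient (ID 0) is non-interacting.  Out-of-range wavelengths raise.
        """
        if tissue_id == 0:
            return AMBIENT_PROPERTIES
        lo, hi = self.wavelength_range
        if not (lo <= wavelength <= hi):
            raise ValueError(
                f"wavelength {wavelength} nm outside table range [{lo}, {hi}] nm"
            )
        try:
            a = self.rows[int(tissue_id)]
        except KeyError:
            raise KeyError(f"no optical-property row for tissue ID {tissue_id}") from None
        vals = [float(np.interp(wavelength, self.wavelengths, a[i])) for i in range(4)]
        return OpticalProperties(*vals)

    def property_arrays(self, wavelength: float, n_labels: int = 16) -> dict[str, np.ndarray]:
        """Per-label lookup arrays at one wavelength for the transport kernel."""
        out = {f: np.zeros(n_labels) for f in _FIELDS}
        out["n"][:] = 1.0
        for tid in self.rows:
            if tid >= n_labels:
                continue
            p = self.properties_at(tid, wavelength)
            for f in _FIELDS:
                out[f][tid] = getattr(p, f)
        return out

    def with_overrides(self, overrides: dict[int, dict[str, float]]) -> "OpticalSpectraTable":
        """Return a new table with per-tissue property overrides applied.

        Override values: ``{tissue_id: {"mu_a": 2.0}}`` multiplies, while
        ``{"n=": 1.4}`` (key suffixed with ``=``) replaces the whole
        spectrum with a constant.
        """
        rows = {tid: a.copy() for tid, a in self.rows.items()}
        for tid, fields in overrides.items():
            tid = int(tid)
            if tid not in rows:
                raise KeyError(f"override for unknown tissue ID {tid}")
            for key, val in fields.items():
                if key.endswith("="):
                    f = key[:-1]
                    rows[tid][_FIELDS.index(f), :] = float(val)
                else:
                    rows[tid][_FIELDS.index(key), :] *= float(val)
        return OpticalSpectraTable(self.wavelengths, rows)

    def to_dataframe(self, names: dict[int, str] | None = None) -> pd.DataFrame:
        recs = []
        for tid in self.tissue_ids:
            a = self.rows[tid]
            for k, wl in enumerate(self.wavelengths):
                recs.append(
                    {
                        "tissue_id": tid,
                        "tissue": (names or {}).get(tid, ""),
                        "wavelength_nm": wl,
                        "mu_a_per_mm": a[0, k],
                        "mu_s_per_mm": a[1, k],
                        "g": a[2, k],
                        "n": a[3, k],
                    }
                )
        return pd.DataFrame.from_records(recs)


def uniform_spectra(
    props: dict[int, OpticalProperties],
    wavelengths=(400.0, 1100.0),
) -> OpticalSpectraTable:
    """Build a table with wavelength-independent properties per tissue."""
    wl = np.asarray(wavelengths, dtype=float)
    rows = {
        tid: np.tile(np.array([[p.mu_a], [p.mu_s], [p.g], [p.n]]), (1, wl.size))
        for tid, p in props.items()
    }
    return OpticalSpectraTable(wl, rows)


# ---------------------------------------------------------------------------
# default literature-style spectra
# ---------------------------------------------------------------------------

# Anchor chromophore absorption spectra, cm^-1, approximate shapes:
# whole blood (oxygenated mix), pure water, and a melanosome power law.
_BLOOD_NM = np.array([400, 420, 450, 500, 550, 575, 600, 650, 700, 750, 800, 850, 900, 950, 1000, 1100], float)
_BLOOD_CM = np.array([1500, 2600, 600, 110, 300, 330, 25, 3.5, 2.0, 2.8, 4.0, 5.3, 6.0, 6.5, 6.0, 3.5], float)
_WATER_NM = np.array([400, 500, 600, 650, 700, 750, 800, 850, 900, 950, 1000, 1050, 1100], float)
_WATER_CM = np.array([0.00058, 0.00025, 0.0023, 0.0032, 0.006, 0.026, 0.02, 0.043, 0.068, 0.45, 0.36, 0.12, 0.18], float)


def _mu_a_blood(nm: np.ndarray) -> np.ndarray:
    return np.interp(nm, _BLOOD_NM, _BLOOD_CM) / 10.0  # -> mm^-1


def _mu_a_water(nm: np.ndarray) -> np.ndarray:
    return np.interp(nm, _WATER_NM, _WATER_CM) / 10.0


def _mu_a_melanin(nm: np.ndarray) -> np.ndarray:
    return 6.6e11 * nm**-3.33 / 10.0


# tissue -> (blood frac, water frac, melanin frac, mu_s'(500nm) mm^-1, power b, g, n)
_TISSUE_RECIPES: dict[int, tuple[float, float, float, float, float, float, float]] = {
    1: (0.005, 0.20, 0.0, 1.8, 0.7, 0.75, 1.44),  # subcutis (adipose)
    2: (0.010, 0.70, 0.0, 1.5, 1.0, 0.90, 1.40),  # Pacinian corpuscle
    3: (0.010, 0.60, 0.0, 2.0, 1.2, 0.90, 1.40),  # nerve
    4: (1.000, 0.00, 0.0, 2.2, 0.9, 0.97, 1.37),  # vein (whole blood)
    5: (1.000, 0.00, 0.0, 2.2, 0.9, 0.97, 1.37),  # artery (whole blood)
    6: (0.005, 0.60, 0.0, 2.5, 1.4, 0.93, 1.50),  # tendon (dense collagen)
    7: (0.005, 0.60, 0.0, 2.4, 1.4, 0.93, 1.50),  # collateral ligament
    8: (0.005, 0.60, 0.0, 2.4, 1.4, 0.93, 1.50),  # volar plate
    9: (0.005, 0.60, 0.0, 2.5, 1.4, 0.93, 1.50),  # pulley A4
    10: (0.010, 0.30, 0.0, 2.4, 0.4, 0.92, 1.55),  # bone (cortical/trabecular mix)
    11: (0.000, 0.70, 0.0, 0.9, 1.3, 0.90, 1.38),  # cartilage
    12: (0.000, 0.99, 0.0, 0.05, 1.0, 0.90, 1.34),  # synovial fluid (clear)
    13: (0.030, 0.80, 0.0, 1.0, 1.0, 0.90, 1.38),  # synovial membrane / capsule
    14: (0.000, 0.20, 0.03, 3.5, 1.5, 0.80, 1.42),  # epidermis (melanin-bearing)
    15: (0.020, 0.50, 0.0, 3.0, 1.3, 0.80, 1.40),  # dermis
}

#: Example arthritic override set: hyperemic, turbid synovial fluid and an
#: absorbing thickened membrane (multiplicative on the healthy table).
ARTHRITIC_OVERRIDES: dict[int, dict[str, float]] = {
    12: {"mu_a": 3.0, "mu_s": 5.0},
    13: {"mu_a": 2.0, "mu_s": 1.5},
}


def default_spectra(step_nm: float = 10.0) -> OpticalSpectraTable:
    """Default optical-property table for the 15 tissues, 400-1100 nm.

    Parametric and replaceable: intended as a plausible default for
    demonstrations, not a measured dataset.
    """
    nm = np.arange(400.0, 1100.0 + step_nm / 2, step_nm)
    blood, water, mel = _mu_a_blood(nm), _mu_a_water(nm), _mu_a_melanin(nm)
    rows = {}
    for tid, (fb, fw, fm, a500, b, g, n) in _TISSUE_RECIPES.items():
        mu_a = fb * blood + fw * water + fm * mel + 0.001
        mu_sp = a500 * (nm / 500.0) ** -b
        mu_s = mu_sp / (1.0 - g)
        rows[tid] = np.vstack([mu_a, mu_s, np.full_like(nm, g), np.full_like(nm, n)])
    return OpticalSpectraTable(nm, rows)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def load_spectra(path) -> OpticalSpectraTable:
    """Load a spectra table from CSV.

    Required columns: ``tissue_id``, ``wavelength_nm``, ``g``, ``n`` and the
    coefficients either as ``mu_a_per_mm``/``mu_s_per_mm`` or as
    ``mu_a_per_cm``/``mu_s_per_cm`` (converted to mm^-1).  Every tissue must
    cover the full shared wavelength grid; duplicated (tissue, wavelength)
    pairs are rejected.
    """
    df = pd.read_csv(path)
    required = {"tissue_id", "wavelength_nm", "g", "n"}
    if not required <= set(df.columns):
        raise ValueError(f"spectra CSV missing columns {sorted(required - set(df.columns))}")
    if {"mu_a_per_mm", "mu_s_per_mm"} <= set(df.columns):
        mu_a, mu_s = df["mu_a_per_mm"], df["mu_s_per_mm"]
    elif {"mu_a_per_cm", "mu_s_per_cm"} <= set(df.columns):
        mu_a, mu_s = df["mu_a_per_cm"] / 10.0, df["mu_s_per_cm"] / 10.0
    else:
        raise ValueError("spectra CSV needs mu_a/mu_s columns in per_mm or per_cm units")
    df = df.assign(_mu_a=mu_a, _mu_s=mu_s)
    if df.duplicated(["tissue_id", "wavelength_nm"]).any():
        dups = df[df.duplicated(["tissue_id", "wavelength_nm"], keep=False)]
        raise ValueError(
            "duplicate (tissue, wavelength) rows: "
            f"{sorted(set(map(tuple, dups[['tissue_id', 'wavelength_nm']].values.tolist())))}"
        )
    wl = np.sort(df["wavelength_nm"].unique().astype(float))
    rows = {}
    for tid, sub in df.groupby("tissue_id"):
        sub = sub.sort_values("wavelength_nm")
        if not np.array_equal(sub["wavelength_nm"].to_numpy(dtype=float), wl):
            raise ValueError(f"tissue {tid} does not cover the shared wavelength grid")
        rows[int(tid)] = np.vstack(
            [sub["_mu_a"], sub["_mu_s"], sub["g"], sub["n"]]
        ).astype(float)
    return OpticalSpectraTable(wl, rows)


def save_spectra(table: OpticalSpectraTable, path, names: dict[int, str] | None = None) -> None:
    table.to_dataframe(names).to_csv(path, index=False)
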