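"""Reading and writing 1D SAS profiles and experiment configurations.

Profiles are the 2- or 3-column ASCII ``.dat`` files used by reduction
pipelines and the SASBDB: ``q  I(q)  [sigma]`` with free-form header lines.
The canonical momentum-transfer unit is inverse Angstroms; files whose
q-range is only plausible in inverse nanometres (q_max > 2) are converted on
read when dialect detection is on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .composition import ACCESSION_PATTERNS, Assembly, Component, SolventSpec

logger = logging.getLogger("sasreport")

_COMMENT_CHARS = ("#", "%", ";")
_NM_Q_THRESHOLD = 2.0  # A^-1; biomolecular q_max rarely exceeds ~1 A^-1


class ProfileFormatError(ValueError):
    """Unparseable or insufficient profile data."""


class ConfigError(ValueError):
    """Invalid experiment configuration."""


@dataclass
class SASProfile:
    """A 1D scattering curve I(q) with optional 1-sigma uncertainties.

    q is in A^-1 and strictly increasing; I is in cm^-1 on absolute scale
    or arbitrary units; sigma (if present) shares I's units.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    intensity_scale: str = "arbitrary"   # or "absolute_cm"
    label: str = ""
    source_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        self.validate()

    def validate(self):
        if self.q.ndim != 1 or len(self.q) != len(self.I):
            raise ProfileFormatError("q and I must be 1D arrays of equal length")
        if len(self.q) < 5:
            raise ProfileFormatError(
                f"insufficient data: {len(self.q)} points (need >= 5)"
            )
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ProfileFormatError("q values must be positive and strictly increasing")
        if self.sigma is not None:
            if len(self.sigma) != len(self.q):
                raise ProfileFormatError("sigma length mismatch")
            if np.any(self.sigma <= 0):
                raise ProfileFormatError("sigma values must be positive")

    def __len__(self):
        return len(self.q)

    def scaled(self, factor: float) -> "SASProfile":
        return SASProfile(
            q=self.q.copy(), I=self.I * factor,
            sigma=None if self.sigma is None else self.sigma * factor,
            intensity_scale=self.intensity_scale, label=self.label,
            source_meta=dict(self.source_meta),
        )

    def window(self, q_min: float | None = None,
               q_max: float | None = None) -> "SASProfile":
        """Sub-profile restricted to [q_min, q_max]."""
        mask = np.ones(len(self.q), dtype=bool)
        if q_min is not None:
            mask &= self.q >= q_min
        if q_max is not None:
            mask &= self.q <= q_max
        return SASProfile(
            q=self.q[mask], I=self.I[mask],
            sigma=None if self.sigma is None else self.sigma[mask],
            intensity_scale=self.intensity_scale, label=self.label,
            source_meta=dict(self.source_meta),
        )


@dataclass
class ModelCurve:
    """A model intensity curve on its own q-grid (no uncertainties)."""

    q: np.ndarray
    I_model: np.ndarray
    scale_fitted: bool = False
    label: str = ""

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I_model = np.asarray(self.I_model, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ProfileFormatError("model curve q must be strictly increasing")


def read_profile(path, dialect: str = "auto") -> SASProfile:
    """Read a 2- or 3-column ASCII profile.

    Header/comment lines (leading '#', '%', ';' or non-numeric text) are
    preserved in ``source_meta``.  Rows with non-finite intensities are
    dropped with a logged count.  With ``dialect='auto'``, q is converted
    from nm^-1 to A^-1 when q_max > 2.
    """
    path = Path(path)
    if dialect not in ("auto", "atsas", "plain"):
        raise ValueError(f"unknown dialect {dialect!r}")
    header_lines: list[str] = []
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(_COMMENT_CHARS):
                header_lines.append(line.lstrip("#%; ").rstrip())
                continue
            parts = line.replace(",", " ").split()
            try:
                values = [float(p) for p in parts[:3]]
            except ValueError:
                if rows:
                    raise ProfileFormatError(
                        f"{path.name}: unparseable data line {lineno}: {line!r}"
                    )
                header_lines.append(line)
                continue
            if len(values) < 2:
                raise ProfileFormatError(
                    f"{path.name}: line {lineno} has fewer than 2 columns"
                )
            rows.append(values)
    if not rows:
        raise ProfileFormatError(f"{path.name}: no numeric data found")
    ncol = min(len(r) for r in rows)
    data = np.array([r[:ncol] for r in rows], dtype=float)
    q, I = data[:, 0], data[:, 1]
    sigma = data[:, 2] if ncol >= 3 else None
    finite = np.isfinite(I) & np.isfinite(q)
    if sigma is not None:
        finite &= np.isfinite(sigma)
    n_dropped = int(np.sum(~finite))
    if n_dropped:
        logger.info("%s: dropped %d rows with non-finite values", path.name, n_dropped)
    q, I = q[finite], I[finite]
    if sigma is not None:
        sigma = sigma[finite]
    if len(q) < 5:
        raise ProfileFormatError(
            f"{path.name}: insufficient data ({len(q)} valid rows, need >= 5)"
        )
    meta = {"header": header_lines, "path": str(path)}
    if dialect == "auto" and q.max() > _NM_Q_THRESHOLD:
        q = q / 10.0
        meta["unit_conversion"] = "nm^-1 -> A^-1 (q divided by 10)"
        logger.info("%s: q_max %.3g suggests nm^-1; converted to A^-1",
                    path.name, q.max() * 10)
    scale = "arbitrary"
    for line in header_lines:
        if "1/cm" in line or "cm^-1" in line or "cm-1" in line:
            scale = "absolute_cm"
    return SASProfile(q=q, I=I, sigma=sigma, intensity_scale=scale,
                      label=path.stem, source_meta=meta)


def read_model_curve(path) -> ModelCurve:
    """Read a 2-column (or 3-column; sigma ignored) model-fit curve."""
    prof = read_profile(path, dialect="plain")
    return ModelCurve(q=prof.q, I_model=prof.I, label=prof.label)


def write_profile(profile: SASProfile, path) -> None:
    """Write a profile; round-trips q, I, sigma to 6 significant digits."""
    path = Path(path)
    lines = [f"# {profile.label}" if profile.label else "# SAS profile"]
    if profile.intensity_scale == "absolute_cm":
        lines.append("# Intensity scale: absolute (1/cm)")
    for extra in profile.source_meta.get("header", []):
        lines.append(f"# {extra}")
    if profile.sigma is None:
        lines.append("#        q              I")
        for qi, ii in zip(profile.q, profile.I):
            lines.append(f"{qi:.6e}  {ii:.6e}")
    else:
        lines.append("#        q              I            sigma")
        for qi, ii, si in zip(profile.q, profile.I, profile.sigma):
            lines.append(f"{qi:.6e}  {ii:.6e}  {si:.6e}")
    path.write_text("\n".join(lines) + "\n")


# ---- experiment configuration ---------------------------------------------


@dataclass
class InstrumentSpec:
    geometry: str = "point"          # or "slit"
    slit_plateau: float = 0.0        # trapezoid plateau half-width, A^-1
    slit_base: float = 0.0           # trapezoid base half-width, A^-1


@dataclass
class ExperimentConfig:
    """Validated experiment description loaded from YAML."""

    samples: list                    # list of Assembly
    solvent: SolventSpec
    concentrations: list             # mg/ml, one per measurement
    instrument: InstrumentSpec
    profiles: list                   # file paths (may be empty)
    options: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


_REQUIRED_KEYS = ("samples", "solvent")


def _component_from_dict(d: dict, warnings: list) -> Component:
    identifiers = d.get("identifiers", {})
    for db, acc in identifiers.items():
        pattern = ACCESSION_PATTERNS.get(db.lower())
        if pattern is not None and not pattern.match(str(acc)):
            msg = f"identifier {acc!r} does not match the {db} accession pattern"
            warnings.append(msg)
            logger.warning(msg)
    mods = [(m["name"] if "name" in m else m["formula"], m.get("count", 1))
            for m in d.get("modifications", [])]
    return Component(
        name=d.get("name", "component"),
        kind=d["kind"],
        sequence=d["sequence"],
        copies=int(d.get("copies", 1)),
        nonexchangeable_deuteration=float(d.get("nonexchangeable_deuteration", 0.0)),
        modifications=mods,
        extra_atoms=d.get("extra_atoms", {}),
        identifiers=identifiers,
    )


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment configuration.

    Identifier strings failing accession patterns produce warnings, not
    errors.  All missing required keys are reported at once.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path.name}: config must be a mapping")
    missing = [k for k in _REQUIRED_KEYS if k not in raw]
    if missing:
        raise ConfigError(
            f"{path.name}: missing required keys: {', '.join(sorted(missing))}"
        )
    warnings: list[str] = []
    samples = []
    for sample in raw["samples"]:
        comps = [_component_from_dict(c, warnings) for c in sample["components"]]
        samples.append(Assembly(comps))
    solv = raw["solvent"]
    solvent = SolventSpec(
        d2o_volume_fraction=float(solv.get("d2o_volume_fraction", 0.0)),
        solutes=solv.get("solutes", []),
    )
    inst = raw.get("instrument", {})
    instrument = InstrumentSpec(
        geometry=inst.get("geometry", "point"),
        slit_plateau=float(inst.get("slit_plateau", 0.0)),
        slit_base=float(inst.get("slit_base", 0.0)),
    )
    profiles = raw.get("profiles", [])
    for p in profiles:
        resolved = (path.parent / p) if not Path(p).is_absolute() else Path(p)
        if not resolved.exists():
            raise ConfigError(f"{path.name}: referenced profile not found: {p}")
    return ExperimentConfig(
        samples=samples,
        solvent=solvent,
        concentrations=raw.get("concentrations", []),
        instrument=instrument,
        profiles=profiles,
        options=raw.get("options", {}),
        warnings=warnings,
    )
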