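"""Receptor-noise-limited colour metrics for a tetrachromatic (UVS avian) viewer.

A stimulus is summarised by the relative quantum catches of the four single
cones (UV, SW, MW, LW) plus the double cone.  From those we compute:

* **luminance** — the double-cone catch itself (avian achromatic channel);
* **saturation** — Euclidean distance from the centre of the tetrahedral colour
  space spanned by the four single-cone classes (0 at the achromatic point,
  0.75 at a vertex under the unit-vertex-distance-0.75 convention used here);
* **hue** — the opponency ratio (LW + UV) / (SW + MW), larger for redder and/or
  more UV-reflective colours;
* **chromatic contrast** — the log-linear receptor-noise-limited (RNL) distance
  between two stimuli in just-noticeable differences (JND);
* **achromatic contrast** — |ln(dblA/dblB)| / ω in JND.

Receptor noise per channel is e_i = ω · sqrt(η_ref / η_i) where ω is the Weber
fraction of the reference (most abundant) cone class and η_i the relative cone
abundances; a simpler ω / sqrt(η_i) convention is selectable.  Two colours at
most 1 JND apart are treated as indiscriminable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, UndefinedHueError

CONE_ORDER = ("uv", "sw", "mw", "lw")

#: Regular-tetrahedron vertices, centre-to-vertex distance 0.75
#: (√6/4 ≈ 0.6123724, √2/4 ≈ 0.3535534, √2/2 ≈ 0.7071068).
TETRA_VERTICES = {
    "uv": np.array([0.0, 0.0, 0.75]),
    "sw": np.array([-math.sqrt(6.0) / 4.0, -math.sqrt(2.0) / 4.0, -0.25]),
    "mw": np.array([math.sqrt(6.0) / 4.0, -math.sqrt(2.0) / 4.0, -0.25]),
    "lw": np.array([0.0, math.sqrt(2.0) / 2.0, -0.25]),
}

_VERTEX_MATRIX = np.stack([TETRA_VERTICES[c] for c in CONE_ORDER])  # (4, 3)


@dataclass(frozen=True)
class ConeCatch:
    """Relative quantum catches of one colour patch.

    All five values must be finite and non-negative; chromatic operations
    (saturation, hue, chromatic contrast) additionally require the four
    single-cone catches to be strictly positive.
    """

    uv: float
    sw: float
    mw: float
    lw: float
    dbl: float

    def __post_init__(self):
        for name in (*CONE_ORDER, "dbl"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidArgumentError(f"cone catch {name}={v!r} must be finite and >= 0")

    def singles(self) -> np.ndarray:
        """The four single-cone catches in UV, SW, MW, LW order."""
        return np.array([self.uv, self.sw, self.mw, self.lw], dtype=float)

    def scaled(self, k: float) -> "ConeCatch":
        """Uniformly intensity-scaled copy (all five catches × k)."""
        if k <= 0:
            raise InvalidArgumentError("scale factor must be > 0")
        return ConeCatch(self.uv * k, self.sw * k, self.mw * k, self.lw * k, self.dbl * k)

    def _require_positive_singles(self, op: str) -> np.ndarray:
        s = self.singles()
        if np.any(s <= 0):
            raise InvalidArgumentError(f"{op} requires strictly positive single-cone catches, got {s}")
        return s


@dataclass(frozen=True)
class VisualSystem:
    """Receiver model: relative cone abundances and the Weber fraction.

    Parameters
    ----------
    abundance
        Relative abundances η for (uv, sw, mw, lw).  Only ratios matter.
    weber
        Weber fraction ω of the reference channel (default 0.05).
    reference_cone
        Channel whose noise equals ω; defaults to the most abundant class.
    convention
        ``"reference"`` (default): e_i = ω·sqrt(η_ref/η_i).
        ``"simple"``: e_i = ω/sqrt(η_i) (no reference normalisation).
    """

    abundance: tuple = (1.0, 1.0, 1.0, 1.0)
    weber: float = 0.05
    reference_cone: str | None = None
    convention: str = "reference"

    def __post_init__(self):
        ab = tuple(float(a) for a in self.abundance)
        if len(ab) != 4 or any(a <= 0 for a in ab):
            raise InvalidArgumentError("abundance must be four positive values (uv, sw, mw, lw)")
        object.__setattr__(self, "abundance", ab)
        if self.weber <= 0:
            raise InvalidArgumentError("Weber fraction must be > 0")
        ref = self.reference_cone
        if ref is None:
            ref = CONE_ORDER[int(np.argmax(ab))]
        if ref not in CONE_ORDER:
            raise InvalidArgumentError(f"reference_cone must be one of {CONE_ORDER}")
        object.__setattr__(self, "reference_cone", ref)
        if self.convention not in ("reference", "simple"):
            raise InvalidArgumentError("convention must be 'reference' or 'simple'")

    def noise(self) -> np.ndarray:
        """Per-channel noise e in (uv, sw, mw, lw) order; e_ref == ω."""
        eta = np.asarray(self.abundance, dtype=float)
        if self.convention == "reference":
            eta_ref = eta[CONE_ORDER.index(self.reference_cone)]
            return self.weber * np.sqrt(eta_ref / eta)
        return self.weber / np.sqrt(eta)


#: Symmetric reference system used throughout the unit tests: no uncited
#: abundance constant is load-bearing there.
SYMMETRIC_VS = VisualSystem()

#: Blue tit (UVS) relative cone abundances as commonly circulated from retinal
#: counts; configuration, not a measured constant of this package.
BLUETIT_VS = VisualSystem(abundance=(0.37, 0.70, 0.99, 1.00), weber=0.05)


def receptor_noise(vs: VisualSystem) -> np.ndarray:
    """Per-cone noise vector of a visual system (see :meth:`VisualSystem.noise`)."""
    return vs.noise()


def luminance(c: ConeCatch) -> float:
    """Perceived lightness: the double-cone catch, unchanged."""
    return float(c.dbl)


def saturation(c: ConeCatch) -> float:
    """Distance from the achromatic centre of tetrahedral colour space.

    Single-cone catches are normalised to proportions; the stimulus position is
    the abundance-weighted vertex average, and saturation its Euclidean norm
    (range [0, 0.75]).  Invariant under uniform intensity scaling.
    """
    s = c._require_positive_singles("saturation")
    p = s / s.sum()
    pos = p @ _VERTEX_MATRIX
    return float(np.linalg.norm(pos))


def hue(c: ConeCatch) -> float:
    """Opponency hue ratio (LW + UV) / (SW + MW)."""
    denom = c.sw + c.mw
    if denom <= 0:
        raise UndefinedHueError("hue undefined: SW + MW catch is zero")
    return float((c.lw + c.uv) / denom)


def chromatic_contrast(a: ConeCatch, b: ConeCatch, vs: VisualSystem = SYMMETRIC_VS) -> float:
    """RNL chromatic distance between two stimuli in JND (log-linear form).

    Δf_i = ln(a_i/b_i) for the four single cones; the tetrachromatic distance is
    sqrt(N/D) with

        N = Σ_{i<j} (Δf_i − Δf_j)² · Π_{k∉{i,j}} e_k²
        D = Σ_i Π_{k≠i} e_k²

    The double cone does not enter.  Zero or negative catches are hard errors.
    """
    fa = np.log(a._require_positive_singles("chromatic contrast"))
    fb = np.log(b._require_positive_singles("chromatic contrast"))
    df = fa - fb
    e2 = vs.noise() ** 2
    num = 0.0
    for i, j in itertools.combinations(range(4), 2):
        others = [k for k in range(4) if k not in (i, j)]
        num += (df[i] - df[j]) ** 2 * np.prod(e2[others])
    den = sum(np.prod(e2[[k for k in range(4) if k != i]]) for i in range(4))
    return float(np.sqrt(num / den))


def achromatic_contrast(a: ConeCatch, b: ConeCatch, vs: VisualSystem = SYMMETRIC_VS) -> float:
    """Luminance contrast |ln(dbl_a / dbl_b)| / ω in JND."""
    if a.dbl <= 0 or b.dbl <= 0:
        raise InvalidArgumentError("achromatic contrast requires positive double-cone catches")
    return float(abs(math.log(a.dbl / b.dbl)) / vs.weber)


def discriminable(jnd: float) -> bool:
    """Whether a contrast exceeds the discrimination threshold (strictly > 1 JND)."""
    if jnd < 0:
        raise InvalidArgumentError("JND values are non-negative")
    return jnd > 1.0


@dataclass(frozen=True)
class ColourMetrics:
    """The full per-individual metric vector used by the statistical screens."""

    luminance: float
    saturation: float
    hue: float
    chromatic_contrast: float
    achromatic_contrast: float
    relative_marking_area: float = field(default=float("nan"))

    def as_dict(self) -> dict:
        return {
            "luminance": self.luminance,
            "saturation": self.saturation,
            "hue": self.hue,
            "chromatic_contrast": self.chromatic_contrast,
            "achromatic_contrast": self.achromatic_contrast,
            "relative_marking_area": self.relative_marking_area,
        }


def metrics_from_catches(
    marking: ConeCatch,
    background: ConeCatch,
    vs: VisualSystem = SYMMETRIC_VS,
    relative_marking_area: float = float("nan"),
) -> ColourMetrics:
    """All colour metrics for a marking patch against its wing background."""
    return ColourMetrics(
        luminance=luminance(marking),
        saturation=saturation(marking),
        hue=hue(marking),
        chromatic_contrast=chromatic_contrast(marking, background, vs),
        achromatic_contrast=achromatic_contrast(marking, background, vs),
        relative_marking_area=relative_marking_area,
    )
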