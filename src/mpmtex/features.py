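"""Per-channel texture features: first-order statistics and GLCM parameters.

Each channel of a FoV is min-max normalized to [0, 1] and described by up
to 17 texture parameters: five first-order statistics of the intensity
distribution (mean, standard deviation, kurtosis, skewness, Shannon
entropy) and, for each of three pixel distances (default 1, 12, 30 px at
1 um/pixel), four gray-level co-occurrence matrix (GLCM) parameters
(contrast, correlation, energy, homogeneity) averaged over the four
orientations 0/45/90/135 degrees.

Conventions (all configurable through :class:`FeatureSpec`):

* GLCM quantization: 8 equal-width gray levels on [0, 1]; pair counting is
  asymmetric by default.
* Kurtosis is the non-excess population moment ratio m4/m2^2 (Gaussian -> 3);
  skewness is m3/m2^1.5; both are defined as 0 on zero-variance rasters.
* Entropy is the Shannon entropy in bits of the 256-bin histogram on [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .types import CHANNELS, FovImage, SampleRecord

log = logging.getLogger(__name__)

FIRST_ORDER = ("mean", "sd", "kurtosis", "skewness", "entropy")
GLCM_FAMILIES = ("contrast", "correlation", "energy", "homogeneity")
ALL_FAMILIES = FIRST_ORDER + GLCM_FAMILIES

#: Unit (row, col) offsets of the four GLCM orientations. For distance d
#: the partner of pixel (r, c) is (r + d*dr, c + d*dc).
ORIENTATION_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

_ENTROPY_BINS = 256


@dataclass(frozen=True)
class FeatureSpec:
    """Named, ordered set of texture parameters per channel.

    ``channels`` maps a channel name to the *feature families* extracted
    from it; second-order families are expanded once per distance.  The
    full family set per channel therefore yields 5 + 4 * len(distances)
    parameters (17 at the default three distances).

    Feature order is fixed: first-order features in their listed order,
    then one block per distance with contrast, correlation, energy,
    homogeneity; channels concatenated in the order CARS, TPEF, SHG.
    """

    channels: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {c: ALL_FAMILIES for c in CHANNELS}
    )
    distances: tuple[int, ...] = (1, 12, 30)
    glcm_levels: int = 8
    glcm_symmetric: bool = False

    def __post_init__(self):
        for ch, fams in self.channels.items():
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")
            bad = set(fams) - set(ALL_FAMILIES)
            if bad:
                raise ValueError(f"unknown feature families {sorted(bad)}")
        if self.glcm_levels < 2:
            raise ValueError("glcm_levels must be >= 2")
        if any(d < 1 for d in self.distances):
            raise ValueError("distances must be >= 1 pixel")

    # -- constructors for the standard candidate subsets ------------------

    @classmethod
    def full(cls, **kw) -> "FeatureSpec":
        """All 17 parameters from each of the three channels (51 total)."""
        return cls(channels={c: ALL_FAMILIES for c in CHANNELS}, **kw)

    @classmethod
    def reduced_shg(cls, **kw) -> "FeatureSpec":
        """Full CARS and TPEF sets plus a reduced 8-parameter SHG set
        (five first-order parameters and contrast at each distance)."""
        return cls(
            channels={
                "cars": ALL_FAMILIES,
                "tpef": ALL_FAMILIES,
                "shg": FIRST_ORDER + ("contrast",),
            },
            **kw,
        )

    @classmethod
    def cars_only(cls, **kw) -> "FeatureSpec":
        """All 17 parameters from the CARS channel alone."""
        return cls(channels={"cars": ALL_FAMILIES}, **kw)

    @classmethod
    def first_order_only(cls, **kw) -> "FeatureSpec":
        return cls(channels={c: FIRST_ORDER for c in CHANNELS}, **kw)

    # -- naming ------------------------------------------------------------

    def channel_features(self, channel: str) -> tuple[str, ...]:
        """Ordered unprefixed feature names for one channel."""
        fams = self.channels.get(channel, ())
        names = [f for f in FIRST_ORDER if f in fams]
        glcm = [f for f in GLCM_FAMILIES if f in fams]
        for d in self.distances:
            names.extend(f"{f}_d{d}" for f in glcm)
        return tuple(names)

    def feature_names(self) -> tuple[str, ...]:
        """Ordered channel-prefixed names of the whole vector."""
        out: list[str] = []
        for ch in CHANNELS:
            if ch in self.channels:
                out.extend(f"{ch}_{f}" for f in self.channel_features(ch))
        return tuple(out)

    def n_features(self) -> int:
        return len(self.feature_names())

    def to_dict(self) -> dict:
        return {
            "channels": {c: list(f) for c, f in self.channels.items()},
            "distances": list(self.distances),
            "glcm_levels": self.glcm_levels,
            "glcm_symmetric": self.glcm_symmetric,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureSpec":
        return cls(
            channels={c: tuple(f) for c, f in d["channels"].items()},
            distances=tuple(d.get("distances", (1, 12, 30))),
            glcm_levels=int(d.get("glcm_levels", 8)),
            glcm_symmetric=bool(d.get("glcm_symmetric", False)),
        )


#: Named standard candidate specs used for model selection.
STANDARD_SPECS = {
    "full": FeatureSpec.full,
    "reduced_shg": FeatureSpec.reduced_shg,
    "cars_only": FeatureSpec.cars_only,
    "first_order_only": FeatureSpec.first_order_only,
}


@dataclass
class FeatureVector:
    """Computed texture parameters of one FoV, with provenance."""

    names: tuple[str, ...]
    values: np.ndarray
    fov_id: str = ""
    patient_id: str = ""
    sample_id: str = ""
    tile_row: int = -1
    tile_col: int = -1
    tissue_label: str | None = None

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# elementary operations


def normalize_channel(raster: np.ndarray, return_degenerate: bool = False):
    """Min-max normalize a raster to [0, 1].

    A constant raster maps to all zeros; this degenerate case is flagged
    (logged, and reported when ``return_degenerate`` is set) so that
    downstream statistics stay finite.
    """
    x = np.asarray(raster, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("raster contains non-finite values")
    lo, hi = x.min(), x.max()
    degenerate = hi == lo
    if degenerate:
        log.warning("constant raster: min-max normalization degenerate, returning zeros")
        out = np.zeros_like(x)
    else:
        out = (x - lo) / (hi - lo)
    return (out, degenerate) if return_degenerate else out


class FirstOrder(NamedTuple):
    mean: float
    sd: float
    kurtosis: float
    skewness: float
    entropy: float


def first_order_features(raster: np.ndarray) -> FirstOrder:
    """First-order statistics of a normalized raster.

    Population moments throughout; on a zero-variance raster skewness and
    kurtosis are defined as 0.  Entropy is Shannon entropy in bits of the
    256-bin equal-width histogram on [0, 1] (empty bins skipped).
    """
    x = np.asarray(raster, dtype=np.float64).ravel()
    mu = x.mean()
    centred = x - mu
    m2 = np.mean(centred**2)
    sd = float(np.sqrt(m2))
    if m2 > 0:
        skew = float(np.mean(centred**3) / m2**1.5)
        kurt = float(np.mean(centred**4) / m2**2)
    else:
        skew = kurt = 0.0
    idx = np.minimum((x * _ENTROPY_BINS).astype(np.intp), _ENTROPY_BINS - 1)
    counts = np.bincount(idx, minlength=_ENTROPY_BINS)
    p = counts[counts > 0] / x.size
    entropy = float(-(p * np.log2(p)).sum())
    return FirstOrder(float(mu), sd, kurt, skew, entropy)


def quantize(raster: np.ndarray, levels: int) -> np.ndarray:
    """Quantize a [0, 1] raster into ``levels`` equal-width gray levels."""
    x = np.asarray(raster, dtype=np.float64)
    return np.minimum((x * levels).astype(np.intp), levels - 1)


def glcm(
    raster: np.ndarray,
    distance: int,
    orientation: int,
    levels: int = 8,
    symmetric: bool = False,
) -> np.ndarray:
    """Gray-level co-occurrence probability matrix of a [0, 1] raster.

    Pixel pairs (p, p + offset) are counted with offsets (row, col):
    0 deg -> (0, +d), 45 deg -> (-d, +d), 90 deg -> (-d, 0),
    135 deg -> (-d, -d); only pairs with both ends inside the raster
    contribute.  Counts are mirrored when ``symmetric`` and normalized to
    sum to 1.
    """
    if orientation not in ORIENTATION_OFFSETS:
        raise ValueError(f"unknown orientation {orientation}; use 0, 45, 90 or 135")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    q = quantize(raster, levels)
    return glcm_from_quantized(q, distance, orientation, levels, symmetric)


def glcm_from_quantized(
    q: np.ndarray, distance: int, orientation: int, levels: int, symmetric: bool
) -> np.ndarray:
    """GLCM from an already-quantized integer raster (internal fast path)."""
    dr, dc = ORIENTATION_OFFSETS[orientation]
    dr, dc = dr * distance, dc * distance
    R, C = q.shape
    rs = slice(max(0, -dr), R - max(0, dr))
    cs = slice(max(0, -dc), C - max(0, dc))
    a = q[rs, cs]
    if a.size == 0:
        raise ValueError(
            f"no valid pairs: distance {distance} exceeds raster extent {q.shape}"
        )
    b = q[rs.start + dr : rs.stop + dr, cs.start + dc : cs.stop + dc]
    counts = np.bincount(
        (a.ravel() * levels + b.ravel()), minlength=levels * levels
    ).astype(np.float64)
    P = counts.reshape(levels, levels)
    if symmetric:
        P = P + P.T
    return P / P.sum()


class GlcmFeatures(NamedTuple):
    contrast: float
    correlation: float
    energy: float
    homogeneity: float


def glcm_features(P: np.ndarray) -> GlcmFeatures:
    """Contrast, correlation, energy and homogeneity of a GLCM.

    correlation = sum_ij P_ij (i - mu_r)(j - mu_c) / (sigma_r sigma_c),
    defined as 0 when either marginal variance vanishes.
    """
    P = np.asarray(P, dtype=np.float64)
    total = P.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"GLCM not normalized (sum = {total})")
    n = P.shape[0]
    i = np.arange(n, dtype=np.float64)
    diff = i[:, None] - i[None, :]
    contrast = float((P * diff**2).sum())
    energy = float((P**2).sum())
    homogeneity = float((P / (1.0 + np.abs(diff))).sum())
    pr, pc = P.sum(axis=1), P.sum(axis=0)
    mu_r, mu_c = float(i @ pr), float(i @ pc)
    var_r = float(((i - mu_r) ** 2) @ pr)
    var_c = float(((i - mu_c) ** 2) @ pc)
    if var_r <= 0 or var_c <= 0:
        correlation = 0.0
    else:
        correlation = float(
            (P * (i[:, None] - mu_r) * (i[None, :] - mu_c)).sum()
            / np.sqrt(var_r * var_c)
        )
    return GlcmFeatures(contrast, correlation, energy, homogeneity)


# ---------------------------------------------------------------------------
# FoV-level extraction


def _channel_values(raster: np.ndarray, families, spec: FeatureSpec) -> list[float]:
    x = normalize_channel(raster)
    values: list[float] = []
    fo = first_order_features(x)
    for name in FIRST_ORDER:
        if name in families:
            values.append(getattr(fo, name))
    glcm_fams = [f for f in GLCM_FAMILIES if f in families]
    if glcm_fams:
        q = quantize(x, spec.glcm_levels)
        for d in spec.distances:
            acc = np.zeros(4)
            for orient in ORIENTATION_OFFSETS:
                P = glcm_from_quantized(
                    q, d, orient, spec.glcm_levels, spec.glcm_symmetric
                )
                acc += np.array(glcm_features(P))
            mean = GlcmFeatures(*(acc / 4.0))
            values.extend(getattr(mean, f) for f in glcm_fams)
    return values


def extract_features(fov: FovImage, spec: FeatureSpec, **provenance) -> FeatureVector:
    """Texture feature vector of one FoV.

    Per channel: min-max normalize, compute the requested first-order
    statistics, then for every distance average each GLCM parameter over
    the four orientations.  Channels are concatenated in CARS, TPEF, SHG
    order.
    """
    values: list[float] = []
    chans = fov.channels()
    for ch in CHANNELS:
        if ch in spec.channels:
            values.extend(_channel_values(chans[ch], spec.channels[ch], spec))
    return FeatureVector(
        names=spec.feature_names(),
        values=np.asarray(values, dtype=np.float64),
        fov_id=fov.fov_id,
        tile_row=fov.tile_row,
        tile_col=fov.tile_col,
        **provenance,
    )


PROVENANCE_COLUMNS = (
    "patient_id",
    "sample_id",
    "fov_id",
    "tile_row",
    "tile_col",
    "tissue_label",
)


def features_table(samples: Sequence[SampleRecord], spec: FeatureSpec) -> pd.DataFrame:
    """Feature table over a cohort: one row per FoV, provenance columns
    followed by one column per named feature."""
    rows = []
    names = spec.feature_names()
    for sample in samples:
        for fov in sample:
            fv = extract_features(
                fov,
                spec,
                patient_id=sample.patient_id,
                sample_id=sample.sample_id,
                tissue_label=sample.tissue_label,
            )
            row = {
                "patient_id": fv.patient_id,
                "sample_id": fv.sample_id,
                "fov_id": fv.fov_id,
                "tile_row": fv.tile_row,
                "tile_col": fv.tile_col,
                "tissue_label": fv.tissue_label,
            }
            row.update(zip(names, fv.values))
            rows.append(row)
    return pd.DataFrame(rows, columns=list(PROVENANCE_COLUMNS) + list(names))
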