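"""Strip-image quantitation: region statistics and reflectance pseudo-absorbance.

A test strip carries a sensing pad (reagent-impregnated, turns blue with
Fe(II)-ferene complex) and a blank reference pad imaged in the same frame.
The colour signal is the decadic pseudo-absorbance of the ratio of mean
region intensities,

    A_c = -log10(I_sensing,c / I_reference,c)

per RGB channel c.  The red channel is the most sensitive reporter for the
blue complex and is selected automatically from a calibration series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ComputationError, ConfigurationError

CHANNELS = ("red", "green", "blue")

#: Default fraction of saturated pixels (0 or 255) above which a QC flag is set.
DEFAULT_SATURATION_THRESHOLD = 0.01


@dataclass(frozen=True)
class RegionSpec:
    """Axis-aligned rectangular region, 0-based, half-open pixel intervals.

    Origin is the image top-left corner; ``x`` grows rightwards along the
    raster width and ``y`` downwards.
    """

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        for name in ("x", "y"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"RegionSpec.{name} must be >= 0")
        for name in ("width", "height"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"RegionSpec.{name} must be > 0")
        if self.width * self.height < 25:
            raise ConfigurationError("RegionSpec.width*height: region area must be >= 25 pixels")

    @property
    def area(self) -> int:
        return self.width * self.height

    def slices(self) -> tuple[slice, slice]:
        """(row, column) slices addressing the region in an (H, W, 3) array."""
        return (slice(self.y, self.y + self.height), slice(self.x, self.x + self.width))

    def within(self, height: int, width: int) -> bool:
        return self.x + self.width <= width and self.y + self.height <= height

    def overlaps(self, other: "RegionSpec") -> bool:
        return not (
            self.x + self.width <= other.x
            or other.x + other.width <= self.x
            or self.y + self.height <= other.y
            or other.y + other.height <= self.y
        )

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "width": self.width, "height": self.height}

    @classmethod
    def from_dict(cls, d: dict) -> "RegionSpec":
        try:
            return cls(x=int(d["x"]), y=int(d["y"]), width=int(d["width"]), height=int(d["height"]))
        except KeyError as exc:
            raise ConfigurationError(f"RegionSpec missing field {exc.args[0]!r}") from exc


def load_regions(path) -> tuple[RegionSpec, RegionSpec]:
    """Read sensing/reference regions from a JSON config file."""
    with open(path) as fh:
        cfg = json.load(fh)
    for key in ("sensing", "reference"):
        if key not in cfg:
            raise ConfigurationError(f"region config missing {key!r} entry")
    return RegionSpec.from_dict(cfg["sensing"]), RegionSpec.from_dict(cfg["reference"])


@dataclass(frozen=True)
class ChannelIntensities:
    """Per-channel mean/SD of 8-bit intensities over one region."""

    mean: tuple[float, float, float]
    sd: tuple[float, float, float]
    n_pixels: int
    saturation_fraction: float


@dataclass(frozen=True)
class AbsorbanceReading:
    """Per-channel pseudo-absorbance of sensing vs reference region."""

    absorbance: dict[str, float]
    channel: str = "red"
    flags: tuple[str, ...] = field(default_factory=tuple)

    def value(self, channel: str | None = None) -> float:
        return self.absorbance[channel or self.channel]


def _as_rgb_array(image) -> np.ndarray:
    pixels = getattr(image, "pixels", image)
    arr = np.asarray(pixels)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ConfigurationError("image must be an (H, W, 3) RGB raster")
    return arr


def region_statistics(image, region: RegionSpec, statistic: str = "mean") -> ChannelIntensities:
    """Summarise one region of an RGB image channel by channel."""
    arr = _as_rgb_array(image)
    h, w = arr.shape[:2]
    if not region.within(h, w):
        raise ConfigurationError("RegionSpec.x/y/width/height: region extends outside the raster")
    patch = arr[region.slices()].astype(float)
    if statistic == "mean":
        centre = patch.reshape(-1, 3).mean(axis=0)
    elif statistic == "median":
        centre = np.median(patch.reshape(-1, 3), axis=0)
    else:
        raise ConfigurationError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    sd = patch.reshape(-1, 3).std(axis=0, ddof=0)
    saturated = np.mean((patch == 0) | (patch == 255))
    return ChannelIntensities(
        mean=tuple(centre), sd=tuple(sd), n_pixels=region.area, saturation_fraction=float(saturated)
    )


def extract_regions(
    image, sensing: RegionSpec, reference: RegionSpec, statistic: str = "mean"
) -> tuple[ChannelIntensities, ChannelIntensities]:
    """Extract sensing and reference region statistics from one strip image.

    The two regions must be disjoint and lie inside the raster.
    """
    if sensing.overlaps(reference):
        raise ConfigurationError("sensing and reference regions overlap")
    return (
        region_statistics(image, sensing, statistic=statistic),
        region_statistics(image, reference, statistic=statistic),
    )


def compute_absorbance(
    sensing: ChannelIntensities,
    reference: ChannelIntensities,
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
) -> AbsorbanceReading:
    """Decadic pseudo-absorbance -log10(I_sensing / I_reference) per channel.

    A sensing intensity of zero yields a +inf sentinel with a flag; a zero
    reference intensity is an error (the ratio is undefined).  Negative
    absorbances (sensing brighter than reference) are allowed and flagged.
    """
    flags: list[str] = []
    absorbance: dict[str, float] = {}
    for i, name in enumerate(CHANNELS):
        i_ref = reference.mean[i]
        i_sens = sensing.mean[i]
        if i_ref <= 0:
            raise ComputationError(f"reference mean intensity is 0 in {name} channel")
        if i_sens <= 0:
            absorbance[name] = np.inf
            flags.append(f"zero_sensing_{name}")
            continue
        a = -np.log10(i_sens / i_ref)
        absorbance[name] = float(a)
        if a < 0:
            flags.append(f"negative_absorbance_{name}")
    if sensing.saturation_fraction > saturation_threshold:
        flags.append("saturated_sensing")
    if reference.saturation_fraction > saturation_threshold:
        flags.append("saturated_reference")
    return AbsorbanceReading(absorbance=absorbance, flags=tuple(flags))


def select_channel(
    readings: list[tuple[float, AbsorbanceReading]],
) -> tuple[str, dict[str, float]]:
    """Pick the reporting channel from a calibration series.

    Fits a per-channel straight line of absorbance on concentration and
    returns the channel with the largest positive slope, with ties broken in
    the fixed order red, green, blue.  All three slopes are returned.
    """
    conc = np.array([c for c, _ in readings], dtype=float)
    if len(np.unique(conc)) < 3:
        raise ConfigurationError("select_channel needs >= 3 distinct concentrations")
    slopes: dict[str, float] = {}
    for name in CHANNELS:
        a = np.array([r.absorbance[name] for _, r in readings], dtype=float)
        slopes[name] = float(np.polyfit(conc, a, 1)[0])
    best = max(CHANNELS, key=lambda ch: (slopes[ch], -CHANNELS.index(ch)))
    return best, slopes


class StripAbsorbanceExtractor(BaseEstimator, TransformerMixin):
    """Transformer turning strip images into per-channel pseudo-absorbances.

    Parameters
    ----------
    sensing_region, reference_region : RegionSpec
        Fixed geometry of the two pads, matching the phone-mount layout.
    statistic : {"mean", "median"}
        Region summary statistic; the arithmetic mean matches a naive
        app implementation, the median is a robust alternative.
    saturation_threshold : float
        Fraction of clipped pixels above which a QC flag is raised.

    ``transform`` maps a sequence of images to an (n, 3) array of
    absorbances in channel order (red, green, blue); per-image
    :class:`AbsorbanceReading` objects are kept in ``readings_``.
    """

    def __init__(
        self,
        sensing_region: RegionSpec | None = None,
        reference_region: RegionSpec | None = None,
        statistic: str = "mean",
        saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
    ):
        self.sensing_region = sensing_region
        self.reference_region = reference_region
        self.statistic = statistic
        self.saturation_threshold = saturation_threshold

    def fit(self, X=None, y=None):  # noqa: D102 - stateless transformer
        if self.sensing_region is None or self.reference_region is None:
            raise ConfigurationError("sensing_region and reference_region must be set")
        if self.sensing_region.overlaps(self.reference_region):
            raise ConfigurationError("sensing and reference regions overlap")
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        self.fit()
        readings = []
        for image in X:
            sens, ref = extract_regions(
                image, self.sensing_region, self.reference_region, statistic=self.statistic
            )
            readings.append(
                compute_absorbance(sens, ref, saturation_threshold=self.saturation_threshold)
            )
        self.readings_ = readings
        return np.array([[r.absorbance[c] for c in CHANNELS] for r in readings])

    def reading(self, image) -> AbsorbanceReading:
        """Convenience: absorbance of a single image."""
        self.transform([image])
        return self.readings_[0]


def quantify_reading(reading: AbsorbanceReading, channel: str = "red") -> AbsorbanceReading:
    """Return a copy of ``reading`` with the reporting channel set."""
    if channel not in CHANNELS:
        raise ConfigurationError(f"channel must be one of {CHANNELS}, got {channel!r}")
    return replace(reading, channel=channel)
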