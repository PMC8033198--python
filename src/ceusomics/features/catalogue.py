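"""Definition of the default 1,044-entry per-image feature catalogue."""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Tuple

FIRST_ORDER_STATS = (
    "mean",
    "median",
    "variance",
    "stddev",
    "skewness",
    "kurtosis",
    "excess_kurtosis",
    "minimum",
    "maximum",
    "range",
    "energy",
    "rms",
    "mean_abs_dev",
    "median_abs_dev",
    "robust_mean_abs_dev",
    "iqr",
    "cv",
    "entropy",
    "uniformity",
    "mode",
    "p10p90_range",
    "quartile_dispersion",
    "total",
)
PERCENTILES = tuple(range(5, 100, 5))  # 5, 10, ..., 95

SHAPE_NAMES = (
    "area",
    "perimeter",
    "perimeter_sq_over_area",
    "circularity",
    "eccentricity",
    "major_axis_length",
    "minor_axis_length",
    "elongation",
    "solidity",
    "extent",
    "equivalent_diameter",
    "compactness",
)

GRADIENT_STATS = (
    "mean",
    "stddev",
    "variance",
    "skewness",
    "kurtosis",
    "minimum",
    "maximum",
    "range",
    "median",
    "p10",
    "p25",
    "p75",
    "p90",
    "iqr",
    "energy",
    "entropy",
    "uniformity",
    "rms",
)

GLCM_FEATURES = (
    "energy",
    "contrast",
    "correlation",
    "entropy",
    "homogeneity",
    "inverse_difference",
    "dissimilarity",
    "max_probability",
    "cluster_shade",
    "cluster_prominence",
    "sum_average",
    "sum_entropy",
    "difference_entropy",
)

GLRLM_FEATURES = (
    "sre",
    "lre",
    "gln",
    "glnn",
    "rln",
    "rlnn",
    "rp",
    "lglre",
    "hglre",
    "srlgle",
    "srhgle",
    "lrlgle",
    "lrhgle",
    "glv",
    "rlv",
    "run_entropy",
)

ANGLES = (0, 45, 90, 135)
ANGULAR_SLOTS = ("a0", "a45", "a90", "a135", "amean", "arange")
GLCM_DISTANCES = (1, 2, 3, 4, 5)
LEVEL_SETTINGS = (32, 64)


@dataclass(frozen=True)
class FeatureEntry:
    name: str
    family: str  # histogram | form_factor | textural | glcm | rlm
    parameters: Tuple[Tuple[str, object], ...] = ()


@dataclass
class FeatureCatalogue:
    entries: List[FeatureEntry]
    _index: Dict[str, FeatureEntry] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("catalogue feature names must be unique")
        self._index = {e.name: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> List[str]:
        return [e.name for e in self.entries]

    def family_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for e in self.entries:
            counts[e.family] = counts.get(e.family, 0) + 1
        return counts

    def manifest(self) -> List[dict]:
        return [
            {"name": e.name, "family": e.family, "parameters": dict(e.parameters)}
            for e in self.entries
        ]


def build_catalogue(
    levels: Tuple[int, ...] = LEVEL_SETTINGS,
    distances: Tuple[int, ...] = GLCM_DISTANCES,
) -> FeatureCatalogue:
    entries: List[FeatureEntry] = []
    for stat in FIRST_ORDER_STATS:
        entries.append(FeatureEntry(f"hist_{stat}", "histogram", (("stat", stat),)))
    for p in PERCENTILES:
        entries.append(FeatureEntry(f"hist_p{p:02d}", "histogram", (("stat", f"p{p:02d}"),)))
    for name in SHAPE_NAMES:
        entries.append(FeatureEntry(f"shape_{name}", "form_factor", (("stat", name),)))
    for stat in GRADIENT_STATS:
        entries.append(FeatureEntry(f"grad_{stat}", "textural", (("stat", stat),)))
    for lv in levels:
        for d in distances:
            for slot in ANGULAR_SLOTS:
                for feat in GLCM_FEATURES:
                    entries.append(
                        FeatureEntry(
                            f"glcm_lv{lv}_d{d}_{slot}_{feat}",
                            "glcm",
                            (("levels", lv), ("distance", d), ("slot", slot), ("feature", feat)),
                        )
                    )
    for lv in levels:
        for slot in ANGULAR_SLOTS:
            for feat in GLRLM_FEATURES:
                entries.append(
                    FeatureEntry(
                        f"rlm_lv{lv}_{slot}_{feat}",
                        "rlm",
                        (("levels", lv), ("slot", slot), ("feature", feat)),
                    )
                )
    return FeatureCatalogue(entries)


@lru_cache(maxsize=1)
def default_catalogue() -> FeatureCatalogue:
    return build_catalogue()


EXPECTED_FAMILY_COUNTS = {
    "histogram": 42,
    "form_factor": 12,
    "textural": 18,
    "glcm": 780,
    "rlm": 192,
}

# the catalogue composition is configuration, but the default must honor the
# published per-image and per-family totals exactly
_cat = default_catalogue()
assert len(_cat) == 1044, f"default catalogue has {len(_cat)} entries, expected 1044"
assert _cat.family_counts() == EXPECTED_FAMILY_COUNTS, _cat.family_counts()
del _cat
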