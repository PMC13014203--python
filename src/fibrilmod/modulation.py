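"""Contact-modulation coefficients k_ij.

For each fibril-native residue pair, k_ij is the ordinary-least-squares
slope of its contact probability P_ij against the ligand:protein molar
ratio across a series of simulated conditions.  Positive k_ij means the
ligand promotes that fibril-native contact in the monomeric ensemble;
negative means it suppresses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactMap
from .errors import IncompatibleMapsError, ParameterError
from .fibrils import NativeContactSet
from .trajectory import LigandCondition


@dataclass
class ModulationEntry:
    slope: float        # probability per unit molar ratio
    intercept: float
    r_squared: float
    n_points: int


@dataclass
class RatioSeries:
    """Contact maps of the same construct at >= 2 distinct ligand ratios."""

    conditions: list[LigandCondition]
    maps: list[ContactMap]
    weights: np.ndarray | None = None  # optional per-condition regression weights

    def __post_init__(self) -> None:
        if len(self.conditions) != len(self.maps):
            raise ParameterError("one map per condition required")
        if len(self.conditions) < 2:
            raise ParameterError("need at least two conditions")
        ratios = {c.ratio for c in self.conditions}
        if len(ratios) < 2:
            raise ParameterError("need at least two distinct ratio values")
        ref = self.maps[0]
        for m in self.maps[1:]:
            if not m.compatible_with(ref):
                raise IncompatibleMapsError("maps differ in cutoff/min_separation")

    @property
    def ratios(self) -> np.ndarray:
        return np.asarray([c.ratio for c in self.conditions], dtype=float)


@dataclass
class ModulationMap:
    """k_ij for fibril-native pairs, keyed by full-length residue numbering."""

    entries: dict[tuple[int, int], ModulationEntry]
    native_source: str
    cutoff: float
    min_separation: int
    n_skipped_out_of_range: int = 0
    conditions: list[LigandCondition] = field(default_factory=list)


def _ols(x: np.ndarray, y: np.ndarray, w: np.ndarray | None) -> tuple[float, float, float]:
    """Weighted least squares line; returns (slope, intercept, r_squared).

    r_squared is nan for a flat response (no variance to explain).
    """
    if w is None:
        w = np.ones_like(x)
    wsum = w.sum()
    xm, ym = (w * x).sum() / wsum, (w * y).sum() / wsum
    sxx = (w * (x - xm) ** 2).sum()
    sxy = (w * (x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_tot = (w * (y - ym) ** 2).sum()
    ss_res = (w * (y - slope * x - intercept) ** 2).sum()
    if ss_tot <= 0:
        r2 = float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def modulation_coefficients(
    series: RatioSeries,
    native: NativeContactSet,
    weighted: bool = False,
) -> ModulationMap:
    """OLS slope of P_ij versus numeric ligand ratio for each native pair.

    Native pairs are given in full-length numbering and mapped onto the
    simulated construct with each map's sequence offset; pairs outside the
    construct range are skipped (counted in ``n_skipped_out_of_range``).  A
    pair absent from a sparse map contributes P_ij = 0 at that condition —
    absence means no frames in contact, a real observation.  ``weighted``
    weights conditions by their frame counts.
    """
    x = series.ratios
    ref = series.maps[0]
    offset = ref.sequence_offset
    n_res = ref.n_residues
    w = (np.asarray([m.n_frames for m in series.maps], dtype=float)
         if weighted else None)
    entries: dict[tuple[int, int], ModulationEntry] = {}
    skipped = 0
    for (fi, fj) in sorted(native.contacts):
        li, lj = fi - offset, fj - offset
        if li < 1 or lj > n_res:
            skipped += 1
            continue
        y = np.asarray([m.probability(li, lj) for m in series.maps])
        slope, intercept, r2 = _ols(x, y, w)
        entries[(fi, fj)] = ModulationEntry(slope, intercept, r2, len(x))
    return ModulationMap(
        entries=entries,
        native_source=native.structure_id,
        cutoff=ref.cutoff,
        min_separation=ref.min_separation,
        n_skipped_out_of_range=skipped,
        conditions=list(series.conditions),
    )


def modulation_map_report(
    mod: ModulationMap,
    sign_threshold: float = 0.0,
    regions: dict[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Classify each native pair as promoted / suppressed / unchanged.

    Pairs with slope > +threshold are promoted, < -threshold suppressed,
    otherwise unchanged.  If ``regions`` maps region names to inclusive
    full-length residue ranges, each pair is annotated with the regions of
    its two residues.
    """
    rows = []
    for (i, j), e in sorted(mod.entries.items()):
        if e.slope > sign_threshold:
            label = "promoted"
        elif e.slope < -sign_threshold:
            label = "suppressed"
        else:
            label = "unchanged"
        row = {
            "i_full": i, "j_full": j, "k": e.slope, "intercept": e.intercept,
            "r2": e.r_squared, "n": e.n_points, "class": label,
        }
        if regions:
            row["region_i"] = _region_of(i, regions)
            row["region_j"] = _region_of(j, regions)
        rows.append(row)
    return pd.DataFrame(rows)


def _region_of(residue: int, regions: dict[str, tuple[int, int]]) -> str:
    for name, (lo, hi) in regions.items():
        if lo <= residue <= hi:
            return name
    return ""


def write_modulation_tsv(mod: ModulationMap, path,
                         sign_threshold: float = 0.0,
                         regions: dict[str, tuple[int, int]] | None = None) -> None:
    df = modulation_map_report(mod, sign_threshold, regions)
    with open(path, "w") as fh:
        fh.write(f"# native_source={mod.native_source}\n")
        fh.write(f"# cutoff_nm={mod.cutoff}\n# min_separation={mod.min_separation}\n")
        ratios = ",".join(str(c.ratio) for c in mod.conditions)
        fh.write(f"# ratios={ratios}\n# sign_threshold={sign_threshold}\n")
        df.to_csv(fh, sep="\t", index=False)
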