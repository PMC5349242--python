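"""Copy-number quantification: global gene/centromere ratio and the
manual FISH scoring rules.

Automated route (DISH): classified signals are tallied per core;
white/blue detections are discarded; the global ratio is all PTEN
divided by all CEP10 signals, capped at 3 to blunt false-positive black
signals; deletion is called at ratio <= 0.60.

Manual route (FISH): per-nucleus PTEN and CEP10 counts from 20-60
intact interphase nuclei.  A nucleus with fewer PTEN than CEP10 signals
is *aberrant*.  Hemizygous deletion: >= 60% of counted nuclei aberrant.
Homozygous deletion: >= one third of aberrant nuclei with zero PTEN
signals (denominator configurable to all counted nuclei).  The ratio
method calls deletion when the pooled PTEN:CEP10 ratio is <= 0.60.
All thresholds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .classification import ClassifiedSignal
from .labels import BLUE, CEP10, CLASSES, MIXED, PTEN, WHITE

__all__ = [
    "QuantConfig",
    "CoreCounts",
    "CoreResult",
    "NucleusCount",
    "FISHScore",
    "tally_counts",
    "global_ratio",
    "fish_percent_aberrant",
    "fish_call",
    "fish_mean_ratio",
    "fish_score",
    "read_nuclei",
    "write_core_results",
]


@dataclass(frozen=True)
class QuantConfig:
    """Ratio cap, deletion threshold and mixed-signal handling."""

    ratio_cap: float = 3.0
    deletion_threshold: float = 0.60
    include_mixed: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.deletion_threshold < self.ratio_cap):
            raise ValueError("require 0 < deletion_threshold < ratio_cap")


@dataclass(frozen=True)
class CoreCounts:
    n_pten: int = 0
    n_cep10: int = 0
    n_mixed: int = 0
    n_white: int = 0
    n_blue: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pten, self.n_cep10, self.n_mixed,
               self.n_white, self.n_blue) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_pten + self.n_cep10 + self.n_mixed + self.n_white + self.n_blue


@dataclass(frozen=True)
class CoreResult:
    """Per-core quantification outcome.

    ``evaluable`` is False when no informative signals exist (no ratio,
    no call); ``capped`` flags a ratio clipped at the cap, including
    the degenerate zero-CEP10 case.
    """

    global_ratio: float | None
    deletion_call: bool | None
    informative_fraction: float
    evaluable: bool = True
    capped: bool = False
    counts: CoreCounts | None = None


@dataclass(frozen=True)
class NucleusCount:
    """Signals counted in one intact interphase nucleus."""

    pten: int
    cep10: int

    def __post_init__(self) -> None:
        if self.pten < 0 or self.cep10 < 0:
            raise ValueError("per-nucleus counts must be >= 0")
        if self.pten != int(self.pten) or self.cep10 != int(self.cep10):
            raise ValueError("per-nucleus counts must be integers")

    @property
    def aberrant(self) -> bool:
        return self.pten < self.cep10


@dataclass(frozen=True)
class FISHScore:
    percent_aberrant: float
    mean_ratio: float | None
    call: str  # normal | hemizygous | homozygous
    ratio_call: str  # no_deletion | deletion | non_evaluable
    adjacent_normal_cells: bool | None = None


def _as_nuclei(nuclei: Iterable) -> list[NucleusCount]:
    out = []
    for n in nuclei:
        if isinstance(n, NucleusCount):
            out.append(n)
        else:
            p, c = n
            out.append(NucleusCount(int(p), int(c)))
    if not out:
        raise ValueError("at least one nucleus count is required")
    return out


def tally_counts(signals: Sequence[ClassifiedSignal | str]) -> CoreCounts:
    """Tally classified signals per class (accepts labels or signals)."""
    counts = dict.fromkeys(CLASSES, 0)
    for s in signals:
        label = s if isinstance(s, str) else s.label
        if label not in counts:
            raise ValueError(f"unknown label {label!r}")
        counts[label] += 1
    return CoreCounts(n_pten=counts[PTEN], n_cep10=counts[CEP10],
                      n_mixed=counts[MIXED], n_white=counts[WHITE],
                      n_blue=counts[BLUE])


def global_ratio(counts: CoreCounts, cfg: QuantConfig | None = None) -> CoreResult:
    """Capped global PTEN:CEP10 ratio and the resulting deletion call.

    Mixed signals are excluded by default; with ``include_mixed`` they
    are added to both the numerator and the denominator.  A core with
    gene signals but no reference signals is reported at the cap and
    flagged; a core with neither is non-evaluable.
    """
    cfg = cfg or QuantConfig()
    num = counts.n_pten
    den = counts.n_cep10
    if cfg.include_mixed:
        num += counts.n_mixed
        den += counts.n_mixed
    informative = counts.n_pten + counts.n_cep10
    informative_fraction = informative / counts.total if counts.total else 0.0

    if num == 0 and den == 0:
        return CoreResult(global_ratio=None, deletion_call=None,
                          informative_fraction=informative_fraction,
                          evaluable=False, counts=counts)
    if den == 0:
        return CoreResult(global_ratio=cfg.ratio_cap, deletion_call=False,
                          informative_fraction=informative_fraction,
                          capped=True, counts=counts)
    ratio = num / den
    capped = ratio > cfg.ratio_cap
    ratio = min(ratio, cfg.ratio_cap)
    return CoreResult(global_ratio=ratio,
                      deletion_call=bool(ratio <= cfg.deletion_threshold),
                      informative_fraction=informative_fraction,
                      capped=capped, counts=counts)


def fish_percent_aberrant(nuclei: Iterable) -> float:
    """Fraction of counted nuclei with fewer PTEN than CEP10 signals."""
    ns = _as_nuclei(nuclei)
    return sum(n.aberrant for n in ns) / len(ns)


def fish_call(nuclei: Iterable, hemi_threshold: float = 0.60,
              homo_threshold: float = 1.0 / 3.0,
              homo_denominator: Literal["aberrant", "counted"] = "aberrant",
              adjacent_normal_cells: bool | None = None) -> str:
    """Deletion call from the percentage-of-aberrant-nuclei method.

    Homozygous takes precedence: at least ``homo_threshold`` of the
    aberrant (or all counted) nuclei show zero PTEN signals.  The
    homozygous definition additionally presumes normal adjacent cells
    carrying one or two PTEN signals -- an observation made at the
    microscope, recorded here as the optional ``adjacent_normal_cells``
    attestation; passing False vetoes the homozygous call.  Otherwise
    hemizygous when the aberrant fraction reaches ``hemi_threshold``,
    else normal.  Both thresholds are inclusive.
    """
    ns = _as_nuclei(nuclei)
    aberrant = [n for n in ns if n.aberrant]
    zero_pten = sum(1 for n in aberrant if n.pten == 0)
    denom = len(aberrant) if homo_denominator == "aberrant" else len(ns)
    if homo_denominator not in ("aberrant", "counted"):
        raise ValueError("homo_denominator must be 'aberrant' or 'counted'")
    if (denom > 0 and zero_pten / denom >= homo_threshold
            and adjacent_normal_cells is not False):
        return "homozygous"
    if len(aberrant) / len(ns) >= hemi_threshold:
        return "hemizygous"
    return "normal"


def fish_mean_ratio(nuclei: Iterable, threshold: float = 0.60,
                    method: Literal["pooled", "mean_of_ratios"] = "pooled",
                    ) -> tuple[float, str]:
    """Mean PTEN:CEP10 ratio over nuclei and its deletion call.

    ``pooled`` (default) divides total PTEN by total CEP10 signals;
    ``mean_of_ratios`` averages per-nucleus ratios over nuclei with at
    least one CEP10 signal.  Deletion is called at ratio <= threshold
    (inclusive).
    """
    ns = _as_nuclei(nuclei)
    if method == "pooled":
        total_cep = sum(n.cep10 for n in ns)
        if total_cep == 0:
            raise ValueError("non-evaluable: zero total CEP10 signals")
        ratio = sum(n.pten for n in ns) / total_cep
    elif method == "mean_of_ratios":
        usable = [n for n in ns if n.cep10 > 0]
        if not usable:
            raise ValueError("non-evaluable: zero total CEP10 signals")
        ratio = sum(n.pten / n.cep10 for n in usable) / len(usable)
    else:
        raise ValueError("method must be 'pooled' or 'mean_of_ratios'")
    return ratio, ("deletion" if ratio <= threshold else "no_deletion")


def fish_score(nuclei: Iterable, hemi_threshold: float = 0.60,
               homo_threshold: float = 1.0 / 3.0,
               homo_denominator: Literal["aberrant", "counted"] = "aberrant",
               ratio_threshold: float = 0.60,
               adjacent_normal_cells: bool | None = None) -> FISHScore:
    """Full FISH scorecard: both scoring methods on one nucleus table."""
    percent = fish_percent_aberrant(nuclei)
    call = fish_call(nuclei, hemi_threshold, homo_threshold, homo_denominator,
                     adjacent_normal_cells)
    try:
        mean_ratio, ratio_call = fish_mean_ratio(nuclei, ratio_threshold)
    except ValueError:
        mean_ratio, ratio_call = None, "non_evaluable"
    return FISHScore(percent_aberrant=percent, mean_ratio=mean_ratio,
                     call=call, ratio_call=ratio_call,
                     adjacent_normal_cells=adjacent_normal_cells)


def read_nuclei(path) -> list[NucleusCount]:
    """Read a nucleus-count TSV with columns nucleus_id, pten, cep10."""
    df = pd.read_csv(Path(path), sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for needed in ("pten", "cep10"):
        if needed not in cols:
            raise ValueError(f"nucleus table missing column {needed!r}")
    return [NucleusCount(int(r[cols["pten"]]), int(r[cols["cep10"]]))
            for _, r in df.iterrows()]


def write_core_results(results: dict[str, CoreResult], path) -> None:
    """Per-core TSV: core_id, counts, global_ratio, deletion_call, ..."""
    rows = []
    for core_id, res in results.items():
        c = res.counts or CoreCounts()
        rows.append({
            "core_id": core_id,
            "n_pten": c.n_pten,
            "n_cep10": c.n_cep10,
            "global_ratio": res.global_ratio,
            "deletion_call": res.deletion_call,
            "informative_fraction": res.informative_fraction,
            "evaluable": res.evaluable,
            "capped": res.capped,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
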