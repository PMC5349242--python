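"""Clinical/survival table schema: validation, dichotomization helpers
and a synthetic cohort generator.

The table is the per-patient master file accompanying the imaging data:
survival times and statuses, tissue type, standard clinico-pathological
dichotomizations (age, BMI, PSA), Gleason and stage groupings, marker
statuses, and the manual FISH scoring results with their dichotomized
codes.  Survival modelling itself is out of scope here -- the module
guarantees the table is analysis-ready.

Dichotomization boundary semantics (inclusive sides as printed in the
data dictionary):

* age_d64: 1 when age >= 64 years
* BMI_d25: 1 when BMI > 25 kg/m^2
* PSA_d10: 1 when PSA >= 10 ng/ml
* PTEN_FISH_ratio_d60: 1 (deletion) when ratio <= 0.6
* PTEN_FISH_percent_d60: 1 (deletion) when percent aberrant >= 0.6

Note: the printed description of the ``pN`` codes ("0: no tumour,
1: positive surgical margin") duplicates the surgical-margin wording of
``R1`` and is likely a transcription slip in the source dictionary; the
field is validated against the printed {0, 1} vocabulary as-is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NUMERIC_RANGES",
    "VOCABULARIES",
    "TISSUE_CODES",
    "COHORT_COUNTS",
    "DISH_SUBSET_COUNTS",
    "ValidationReport",
    "validate_clinical",
    "dichotomize",
    "cohort_summary",
    "synth_clinical",
    "read_clinical",
    "write_clinical",
]

#: inclusive numeric ranges (canonical lower-case field name -> (lo, hi))
NUMERIC_RANGES: dict[str, tuple[float, float]] = {
    "rfs": (0, 163),
    "os": (0, 167),
    "pten_fish_ratio": (0.28, 1.00),
    "pten_fish_percent_ab_nucl": (0.0, 1.00),
    "pten_total_signals": (10, 123),
    "nuclei_number": (9, 40),
    "cep10_total_signals": (17, 127),
}

#: controlled vocabularies for categorical fields
VOCABULARIES: dict[str, set[int]] = {
    "st_rfs": {0, 1, 3},
    "st_os_gen": {0, 1},
    "st_os_spec": {0, 1},
    "tiss": {1, 2, 3, 4, 8},
    "age_d64": {0, 1},
    "bmi_d25": {0, 1},
    "gle_t": {1, 2, 3},
    "pt_t": {1, 2, 3},
    "pn": {0, 1},
    "r1": {0, 1},
    "psa_d10": {0, 1},
    "pten_cyt": {0, 1, 2, 3},
    "spop": {0, 1},
    "erg": {0, 1},
    "pten_fish_ratio_d60": {0, 1},
    "pten_fish_percent_d60": {0, 1},
}

#: integer-valued count fields
_INTEGER_FIELDS = {"pten_total_signals", "nuclei_number", "cep10_total_signals"}

#: tissue code -> name
TISSUE_CODES = {1: "RPE", 2: "CRPC", 3: "LNM", 4: "DM", 8: "BPH"}

#: full-cohort composition by tissue type (sums to 424)
COHORT_COUNTS = {"RPE": 339, "CRPC": 28, "LNM": 17, "DM": 11, "BPH": 29}

#: composition of the imaging subset (sums to 71)
DISH_SUBSET_COUNTS = {"RPE": 38, "CRPC": 10, "LNM": 6, "DM": 1, "BPH": 16}

#: dichotomization rules: variable -> (direction, cutoff); direction is
#: the comparison that maps to code 1
_DICHOTOMIZE_RULES: dict[str, tuple[str, float]] = {
    "age_d64": ("ge", 64.0),
    "bmi_d25": ("gt", 25.0),
    "psa_d10": ("ge", 10.0),
    "pten_fish_ratio_d60": ("le", 0.6),
    "pten_fish_percent_d60": ("ge", 0.6),
}

#: canonical output column order, with the data dictionary's casing
_CANONICAL_COLUMNS = [
    "TMA", "rfs", "st_rfs", "os", "st_os_gen", "st_os_spec", "tiss",
    "age_d64", "BMI_d25", "GLE_t", "pT_t", "pN", "R1", "PSA_d10",
    "PTEN_cyt", "SPOP", "ERG", "PTEN_FISH_ratio", "PTEN_FISH_ratio_d60",
    "PTEN_FISH_percent_ab_nucl", "PTEN_FISH_percent_d60",
    "PTEN_total_signals", "nuclei_number", "CEP10_total_signals",
]


@dataclass
class ValidationReport:
    """Outcome of validate_clinical: violations plus cohort composition."""

    violations: pd.DataFrame  # columns: row, field, violation
    counts_by_tissue: dict[str, int]
    n_rows: int

    @property
    def ok(self) -> bool:
        return self.violations.empty

    def write(self, path) -> None:
        self.violations.to_csv(path, sep="\t", index=False)


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    if isinstance(v, str) and v.strip() == "":
        return True
    return pd.isna(v)


def _lower_columns(table: pd.DataFrame) -> dict[str, str]:
    return {c.lower().strip(): c for c in table.columns}


def validate_clinical(table: pd.DataFrame) -> ValidationReport:
    """Check every field against its printed range or vocabulary.

    Also cross-checks dichotomized fields against their continuous
    source when both are present (ratio <= 0.6 must be coded 1; percent
    aberrant >= 0.6 must be coded 1).  Missing values are permitted
    everywhere except the TMA identifier.
    """
    colmap = _lower_columns(table)
    if "tma" not in colmap:
        raise ValueError("clinical table is missing the mandatory TMA column")

    problems: list[tuple[int, str, str]] = []

    def check_numeric(i, name, value):
        lo, hi = NUMERIC_RANGES[name]
        try:
            v = float(value)
        except (TypeError, ValueError):
            problems.append((i, name, f"not numeric: {value!r}"))
            return None
        if not (lo <= v <= hi):
            problems.append((i, name, f"value {v} outside [{lo}, {hi}]"))
        if name in _INTEGER_FIELDS and v != int(v):
            problems.append((i, name, f"value {v} is not an integer"))
        return v

    def check_vocab(i, name, value):
        try:
            v = int(float(value))
            if float(value) != v:
                raise ValueError
        except (TypeError, ValueError):
            problems.append((i, name, f"not an integer code: {value!r}"))
            return None
        if v not in VOCABULARIES[name]:
            problems.append(
                (i, name, f"code {v} not in {sorted(VOCABULARIES[name])}"))
        return v

    for i, row in table.iterrows():
        if _is_missing(row[colmap["tma"]]):
            problems.append((i, "tma", "missing TMA identifier"))
        values: dict[str, float | None] = {}
        for name in NUMERIC_RANGES:
            if name in colmap and not _is_missing(row[colmap[name]]):
                values[name] = check_numeric(i, name, row[colmap[name]])
        for name in VOCABULARIES:
            if name in colmap and not _is_missing(row[colmap[name]]):
                values[name] = check_vocab(i, name, row[colmap[name]])

        # dichotomization consistency
        for cont, dich in (("pten_fish_ratio", "pten_fish_ratio_d60"),
                           ("pten_fish_percent_ab_nucl", "pten_fish_percent_d60")):
            cv, dv = values.get(cont), values.get(dich)
            if cv is None or dv is None:
                continue
            expected = dichotomize(cv, dich)
            if int(dv) != expected:
                problems.append((
                    i, dich,
                    f"inconsistent with {cont}={cv}: expected code {expected}",
                ))

    tissue_counts = dict.fromkeys(TISSUE_CODES.values(), 0)
    if "tiss" in colmap:
        for v in table[colmap["tiss"]].dropna():
            try:
                code = int(float(v))
            except (TypeError, ValueError):
                continue
            if code in TISSUE_CODES:
                tissue_counts[TISSUE_CODES[code]] += 1

    return ValidationReport(
        violations=pd.DataFrame(problems, columns=["row", "field", "violation"]),
        counts_by_tissue=tissue_counts,
        n_rows=len(table),
    )


def dichotomize(value: float, variable: str | None = None, *,
                cutoff: float | None = None,
                direction: str | None = None) -> int:
    """Map a continuous value to its 0/1 code.

    Either name a known ``variable`` (age_d64, BMI_d25, PSA_d10,
    PTEN_FISH_ratio_d60, PTEN_FISH_percent_d60; case-insensitive) to use
    its printed boundary semantics, or give an explicit ``cutoff`` and
    ``direction`` in {ge, gt, le, lt} (the side that codes 1).
    """
    if variable is not None:
        key = variable.lower().strip()
        if key not in _DICHOTOMIZE_RULES:
            raise KeyError(
                f"unknown dichotomization variable {variable!r}; known: "
                + ", ".join(sorted(_DICHOTOMIZE_RULES))
            )
        direction, cutoff = _DICHOTOMIZE_RULES[key]
    if cutoff is None or direction is None:
        raise ValueError("give a variable name, or both cutoff and direction")
    v = float(value)
    ops = {"ge": v >= cutoff, "gt": v > cutoff, "le": v <= cutoff, "lt": v < cutoff}
    if direction not in ops:
        raise ValueError("direction must be one of ge, gt, le, lt")
    return int(ops[direction])


def cohort_summary(table: pd.DataFrame) -> dict:
    """Cohort composition: counts per tissue type and their total."""
    colmap = _lower_columns(table)
    counts = dict.fromkeys(TISSUE_CODES.values(), 0)
    if "tiss" in colmap:
        for v in table[colmap["tiss"]].dropna():
            code = int(float(v))
            if code in TISSUE_CODES:
                counts[TISSUE_CODES[code]] += 1
    return {"counts": counts, "total": int(sum(counts.values()))}


def synth_clinical(n: int, seed: int = 0,
                   tissue_counts: dict[str, int] | None = None) -> pd.DataFrame:
    """Generate a synthetic, schema-valid clinical table of ``n`` rows.

    Continuous quantities (age, BMI, PSA, FISH counts) are sampled
    within realistic ranges and the dichotomized codes derived from
    them, so the output always validates cleanly.  Tissue types follow
    the full-cohort proportions unless ``tissue_counts`` overrides
    them; when the override sums exactly to ``n`` the composition is
    reproduced exactly (rows shuffled), otherwise it is used as
    sampling weights.  Deterministic per seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    weights = tissue_counts or COHORT_COUNTS
    unknown = [name for name in weights if name not in TISSUE_CODES.values()]
    if unknown:
        raise ValueError("unknown tissue type(s): " + ", ".join(unknown))
    codes = {v: k for k, v in TISSUE_CODES.items()}
    tissue_codes = np.asarray([codes[name] for name in weights])
    p = np.asarray(list(weights.values()), float)
    if (p < 0).any() or p.sum() <= 0:
        raise ValueError("tissue counts must be non-negative with a positive sum")
    exact = tissue_counts is not None and int(p.sum()) == n \
        and all(float(v).is_integer() for v in p)
    p = p / p.sum()

    # unique TMA core ids: blocks of 8 columns x 13 rows
    blocks = [chr(ord("A") + i) for i in range(26)]
    per_block = 8 * 13
    ids = []
    bi = 0
    while len(ids) < n:
        block = blocks[bi % len(blocks)] * (bi // len(blocks) + 1)
        ids.extend(f"{block}_{c}_{r}" for r in range(1, 14) for c in range(1, 9))
        bi += 1
    ids = ids[:n]

    if n:
        if exact:
            tiss = np.repeat(tissue_codes,
                             [int(v) for v in weights.values()])
            rng.shuffle(tiss)
        else:
            tiss = rng.choice(tissue_codes, size=n, p=p)
        age = rng.uniform(45, 80, n)
        bmi = rng.uniform(18, 35, n)
        psa = rng.uniform(0.5, 40, n)
        nuclei = rng.integers(9, 41, n)
        # roughly two reference signals per nucleus
        cep10 = np.clip(np.rint(nuclei * rng.uniform(1.8, 3.2, n)), 17, 127).astype(int)
        ratio_target = rng.uniform(0.28, 1.0, n)
        pten_lo = np.maximum(10, np.ceil(0.28 * cep10)).astype(int)
        pten = np.clip(np.rint(ratio_target * cep10), pten_lo, cep10).astype(int)
        ratio = pten / cep10
        percent_ab = np.clip(1.0 - ratio + rng.normal(0.0, 0.08, n), 0.0, 1.0)
        st_os_gen = rng.integers(0, 2, n)
        df = pd.DataFrame({
            "TMA": ids,
            "rfs": rng.integers(0, 164, n),
            "st_rfs": rng.choice([0, 1, 3], n, p=[0.6, 0.3, 0.1]),
            "os": rng.integers(0, 168, n),
            "st_os_gen": st_os_gen,
            "st_os_spec": st_os_gen * rng.integers(0, 2, n),
            "tiss": tiss,
            "age_d64": [dichotomize(a, "age_d64") for a in age],
            "BMI_d25": [dichotomize(b, "BMI_d25") for b in bmi],
            "GLE_t": rng.choice([1, 2, 3], n, p=[0.3, 0.45, 0.25]),
            "pT_t": rng.choice([1, 2, 3], n, p=[0.5, 0.4, 0.1]),
            "pN": rng.integers(0, 2, n),
            "R1": rng.integers(0, 2, n),
            "PSA_d10": [dichotomize(v, "PSA_d10") for v in psa],
            "PTEN_cyt": rng.integers(0, 4, n),
            "SPOP": rng.choice([0, 1], n, p=[0.9, 0.1]),
            "ERG": rng.integers(0, 2, n),
            "PTEN_FISH_ratio": ratio,
            "PTEN_FISH_ratio_d60": [dichotomize(r, "PTEN_FISH_ratio_d60")
                                    for r in ratio],
            "PTEN_FISH_percent_ab_nucl": percent_ab,
            "PTEN_FISH_percent_d60": [dichotomize(v, "PTEN_FISH_percent_d60")
                                      for v in percent_ab],
            "PTEN_total_signals": pten,
            "nuclei_number": nuclei,
            "CEP10_total_signals": cep10,
        })
    else:
        df = pd.DataFrame(columns=_CANONICAL_COLUMNS)
    return df[_CANONICAL_COLUMNS]


def read_clinical(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def write_clinical(table: pd.DataFrame, path) -> None:
    """Write TSV/CSV; missing values become empty fields, never sentinels."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    table.to_csv(path, sep=sep, index=False, na_rep="")
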