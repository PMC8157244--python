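"""Virtual breast-cancer populations with CYP2D6 activity-score distributions.

CYP2D6 diplotype activity is summarised by the activity score (AS): each
allele contributes 0 (no function), 0.5 (decreased) or 1 (normal function),
and gene duplications push the diplotype sum above 2.  For simulation the
continuum of diplotype scores is collapsed into six classes
``0, 0.5, 1, 1.5, 2, >2`` and every virtual patient carries one class plus
an age, a body weight and two log-scale random effects on the tamoxifen
clearance pathways.

Nine biogeographical groups (the standardized ancestry-based groupings used
to organise pharmacogene allele frequencies) each get their own categorical
AS distribution; a bundled frequency table ships with the package.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The six activity-score classes, in increasing-activity order.
AS_CLASSES: tuple[str, ...] = ("0", "0.5", "1", "1.5", "2", ">2")

_AS_INDEX = {c: i for i, c in enumerate(AS_CLASSES)}

#: The nine biogeographical groups, in the canonical (bundled-table) order.
GROUPS: tuple[str, ...] = (
    "American",
    "African American/Afro-Caribbean",
    "Central/South Asian",
    "East Asian",
    "European",
    "Latino",
    "Near Eastern",
    "Oceanian",
    "Sub-Saharan African",
)

GROUP_INDEX = {g: i for i, g in enumerate(GROUPS)}

PHENOTYPES: tuple[str, ...] = ("gPM", "gIM", "gNM")

# AS 0 -> poor metabolizer; 0.5-1 -> intermediate; >=1.5 -> normal
# (ultrarapid metabolizers are folded into gNM).
_PHENOTYPE_BY_CLASS = {
    "0": "gPM",
    "0.5": "gIM",
    "1": "gIM",
    "1.5": "gNM",
    "2": "gNM",
    ">2": "gNM",
}

_BUNDLED_FREQUENCY_RESOURCE = "as_frequencies.csv"


def as_class_label(value: object) -> str:
    """Canonical class label for an activity-score value.

    Accepts one of the six class labels (as string) or the equivalent
    number (``2``, ``2.0`` -> ``"2"``).  Raises ``ValueError`` otherwise.
    """
    if isinstance(value, str):
        label = value.strip()
        if label in _AS_INDEX:
            return label
        try:
            value = float(label)
        except ValueError:
            raise ValueError(f"unknown activity-score class {value!r}") from None
    num = float(value)  # type: ignore[arg-type]
    for label in AS_CLASSES[:-1]:
        if num == float(label):
            return label
    raise ValueError(f"unknown activity-score class {value!r}")


def genotype_to_phenotype(score: str) -> str:
    """Map an activity-score class to the genotype-predicted phenotype.

    0 -> gPM, 0.5/1 -> gIM, 1.5/2/>2 -> gNM.  Total and deterministic.
    """
    return _PHENOTYPE_BY_CLASS[as_class_label(score)]


@dataclass(frozen=True)
class RawFrequencyRecord:
    """One row of a raw AS frequency sheet.

    ``score_label`` supports the 0.25-step diplotype labels (``"0"``,
    ``"0.25"``, ... up to ``"6"``) plus ``"missing"`` for patients without
    AS information.
    """

    group: str
    score_label: str
    frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(
                f"frequency {self.frequency!r} for {self.group}/{self.score_label} "
                "outside [0, 1]"
            )


@dataclass(frozen=True)
class ASFrequencyTable:
    """Six-class activity-score distribution for one group.

    ``missing_assigned`` audits the probability mass moved into class 2 by
    the missing-AS rule (explicit ``missing`` records plus any shortfall of
    the raw frequencies to 1).
    """

    group: str
    freq: Mapping[str, float]
    missing_assigned: float = 0.0

    def __post_init__(self) -> None:
        if set(self.freq) != set(AS_CLASSES):
            raise ValueError(
                f"frequency table for {self.group!r} must cover exactly "
                f"the classes {AS_CLASSES}"
            )
        if any(v < 0 for v in self.freq.values()):
            raise ValueError(f"negative frequency in table for {self.group!r}")
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"frequencies for {self.group!r} sum to {total!r}, not 1"
            )

    def as_array(self) -> np.ndarray:
        """Frequencies as a vector in class order."""
        return np.array([self.freq[c] for c in AS_CLASSES], dtype=float)

    def phenotype_freq(self) -> dict[str, float]:
        """Exact phenotype proportions implied by the class frequencies."""
        out = {p: 0.0 for p in PHENOTYPES}
        for c, f in self.freq.items():
            out[genotype_to_phenotype(c)] += f
        return out


def _route_raw_label(label: str) -> str | None:
    """Destination class for a raw score label; ``None`` for ``missing``.

    Remapping rules: each 0.25 step is folded into the following 0.5 step
    (0.25->0.5, 0.75->1, 1.25->1.5, 1.75->2); scores of 2.5 and above
    (copy-number variants) are aggregated into ``>2``; 2.25 is routed to
    ``>2`` to keep the six-class partition.
    """
    text = str(label).strip()
    if text.lower() == "missing":
        return None
    if text == ">2":
        return ">2"
    try:
        value = float(text)
    except ValueError:
        raise ValueError(f"unknown activity-score label {label!r}") from None
    if value < 0 or value > 8 or round(value / 0.25) != value / 0.25:
        raise ValueError(f"unknown activity-score label {label!r}")
    if value >= 2.25:
        return ">2"
    if value in (0.0, 0.5, 1.0, 1.5, 2.0):
        return as_class_label(value)
    # a 0.25 step below 2: fold into the next 0.5 step
    return as_class_label(value + 0.25)


def normalize_frequency_table(
    records: Iterable[RawFrequencyRecord],
    group: str,
    *,
    tolerance: float = 2e-3,
) -> ASFrequencyTable:
    """Collapse raw AS frequency records into the six-class table for ``group``.

    Applies the remapping rules of :func:`_route_raw_label`, then assigns the
    ``missing`` mass and any shortfall of the total to 1 to class 2 (missing
    AS information is treated as wildtype).  A total slightly above 1 (up to
    ``tolerance``, as happens with frequencies printed at three significant
    figures) is rescaled proportionally; a larger excess is rejected.
    """
    selected = [r for r in records if r.group == group]
    if not selected:
        raise ValueError(f"no frequency records for group {group!r}")

    freq = {c: 0.0 for c in AS_CLASSES}
    missing_mass = 0.0
    for rec in selected:
        dest = _route_raw_label(rec.score_label)
        if dest is None:
            missing_mass += rec.frequency
        else:
            freq[dest] += rec.frequency

    total = sum(freq.values()) + missing_mass
    if total > 1.0 + tolerance:
        raise ValueError(
            f"frequencies for {group!r} sum to {total:.6f} > 1 + {tolerance}"
        )
    shortfall = max(0.0, 1.0 - total)
    moved = missing_mass + shortfall
    freq["2"] += moved

    scale = sum(freq.values())
    freq = {c: v / scale for c, v in freq.items()}
    return ASFrequencyTable(group=group, freq=freq, missing_assigned=moved / scale)


def load_frequency_records(path) -> list[RawFrequencyRecord]:
    """Read raw frequency records from a CSV with columns group, as_class, frequency."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                RawFrequencyRecord(
                    group=row["group"],
                    score_label=row["as_class"],
                    frequency=float(row["frequency"]),
                )
            )
    return records


def load_bundled_frequency_tables() -> dict[str, ASFrequencyTable]:
    """The package's per-group AS frequency tables, normalized.

    The bundled CSV holds the published six-class frequencies for the nine
    virtual populations (three significant figures, as printed); each group
    is passed through :func:`normalize_frequency_table` so the tables sum to
    one exactly.
    """
    ref = resources.files("tamsim.data").joinpath(_BUNDLED_FREQUENCY_RESOURCE)
    with resources.as_file(ref) as path:
        records = load_frequency_records(path)
    return {g: normalize_frequency_table(records, g) for g in GROUPS}


@dataclass(frozen=True)
class VirtualPatient:
    """One simulated individual."""

    patient_id: int
    group: str
    activity_score: str
    age: float
    weight: float
    eta_cl20: float
    eta_cl23: float

    @property
    def phenotype(self) -> str:
        return genotype_to_phenotype(self.activity_score)


def largest_remainder_counts(freq: Sequence[float], n: int) -> np.ndarray:
    """Integer allocation of ``n`` over categories with proportions ``freq``.

    Largest-remainder (Hamilton) rounding: floor each quota, then hand the
    remaining units to the largest fractional parts, breaking ties by
    category order (lowest index first).  Guarantees
    ``|count_i - freq_i * n| < 1`` and ``sum(counts) == n``.
    """
    quotas = np.asarray(freq, dtype=float) * n
    counts = np.floor(quotas).astype(int)
    leftover = n - int(counts.sum())
    if leftover > 0:
        remainders = quotas - counts
        # stable sort on -remainder keeps ties in index order
        order = np.argsort(-remainders, kind="stable")
        counts[order[:leftover]] += 1
    return counts


def as_class_counts(
    table: ASFrequencyTable,
    n: int,
    assignment_mode: str = "quota",
    rng: np.random.Generator | None = None,
) -> dict[str, int]:
    """Per-class patient counts for a population of size ``n``.

    ``quota`` mode allocates deterministically by largest remainder;
    ``multinomial`` draws the counts at random with expectation freq * n.
    """
    if n <= 0:
        raise ValueError("population size must be >= 1")
    probs = table.as_array()
    if assignment_mode == "quota":
        counts = largest_remainder_counts(probs, n)
    elif assignment_mode == "multinomial":
        if rng is None:
            raise ValueError("multinomial mode needs a random generator")
        counts = rng.multinomial(n, probs / probs.sum())
    else:
        raise ValueError(f"unknown assignment mode {assignment_mode!r}")
    return {c: int(k) for c, k in zip(AS_CLASSES, counts)}


def build_population(
    table: ASFrequencyTable,
    n: int,
    covariate_pool: pd.DataFrame,
    assignment_mode: str = "quota",
    seed=0,
    *,
    omega2_cl20: float = 0.0,
    omega2_cl23: float = 0.0,
    id_offset: int = 0,
) -> list[VirtualPatient]:
    """Build a virtual population of ``n`` patients from a frequency table.

    Activity scores are assigned per :func:`as_class_counts` (patients are
    ordered by class, so quota mode yields seed-independent AS counts and
    assignments).  Age and body weight are sampled independently, with
    replacement, from ``covariate_pool`` (columns ``age_years`` and
    ``weight_kg``).  The two log-scale random effects on the tamoxifen
    clearance pathways are drawn here as zero-mean normals with the supplied
    variances so a population is self-contained.

    ``seed`` may be an int or a sequence of ints (entropy for numpy's
    ``default_rng``); identical seed and inputs give identical populations.
    """
    if covariate_pool.empty:
        raise ValueError("covariate pool is empty")
    rng = np.random.default_rng(seed)
    counts = as_class_counts(table, n, assignment_mode, rng)
    scores: list[str] = []
    for c in AS_CLASSES:
        scores.extend([c] * counts[c])

    ages = covariate_pool["age_years"].to_numpy()
    weights = covariate_pool["weight_kg"].to_numpy()
    age_draw = ages[rng.integers(0, len(ages), size=n)]
    wt_draw = weights[rng.integers(0, len(weights), size=n)]
    eta20 = rng.normal(0.0, np.sqrt(omega2_cl20), size=n)
    eta23 = rng.normal(0.0, np.sqrt(omega2_cl23), size=n)

    return [
        VirtualPatient(
            patient_id=id_offset + i,
            group=table.group,
            activity_score=scores[i],
            age=float(age_draw[i]),
            weight=float(wt_draw[i]),
            eta_cl20=float(eta20[i]),
            eta_cl23=float(eta23[i]),
        )
        for i in range(n)
    ]


def population_to_frame(patients: Sequence[VirtualPatient]) -> pd.DataFrame:
    """Tabular view of a population (one row per patient)."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "group": [p.group for p in patients],
            "activity_score": [p.activity_score for p in patients],
            "phenotype": [p.phenotype for p in patients],
            "age_years": [p.age for p in patients],
            "weight_kg": [p.weight for p in patients],
            "eta_cl20": [p.eta_cl20 for p in patients],
            "eta_cl23": [p.eta_cl23 for p in patients],
        }
    )


def phenotype_percentages(patients: Sequence[VirtualPatient]) -> dict[str, float]:
    """Observed phenotype frequencies of a population, in percent."""
    n = len(patients)
    if n == 0:
        raise ValueError("empty population")
    counts = {p: 0 for p in PHENOTYPES}
    for pat in patients:
        counts[pat.phenotype] += 1
    return {p: 100.0 * k / n for p, k in counts.items()}
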