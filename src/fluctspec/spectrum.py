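"""Mutation-spectrum classification, run context, and rate partitioning.

Mutation calls from Sanger-sequenced reporter alleles are classified into
the standard spectrum categories (base substitution, 1-bp deletion, 1-bp
insertion, complex, other), annotated with the length of the mononucleotide
run containing the event — the signature context of polymerase-slippage
indels that mismatch repair normally corrects — and combined with a total
mutation rate to yield per-category rates, relative rates against a
reference genotype, and repair efficiencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence
import warnings

from ._util import round_sig

__all__ = [
    "CATEGORIES",
    "MutationRecord",
    "MutationSpectrum",
    "RatePartition",
    "scan_runs",
    "classify_mutation",
    "classify_isolate",
    "annotate_run_context",
    "fraction_in_runs",
    "partition_rates",
    "relative_rates",
    "repair_efficiency",
]

#: Canonical spectrum categories, in reporting order.
CATEGORIES = (
    "base substitution",
    "1-bp deletion",
    "1-bp insertion",
    "complex",
    "other",
)

#: Two events in one isolate at most this many bases apart form one complex
#: mutation (clustered changes arising as a single event).
DEFAULT_COMPLEX_WINDOW = 10


@dataclass(frozen=True)
class MutationRecord:
    """One sequence change in one mutant isolate.

    position is 1-based on the reference ORF plus strand.  Exactly one of
    ref_allele/alt_allele may be empty: empty alt is a deletion, empty ref an
    insertion (inserted before ``position``).  run_length is the maximal
    mononucleotide-run length at the (left-normalized) event site, 1 when
    the site is not in a run.
    """

    isolate_id: str
    position: int
    ref_allele: str
    alt_allele: str
    category: str | None = None
    run_length: int | None = None

    def __post_init__(self) -> None:
        if self.ref_allele == "" and self.alt_allele == "":
            raise ValueError("ref and alt alleles cannot both be empty")
        if self.position < 1:
            raise ValueError("positions are 1-based")


@dataclass
class MutationSpectrum:
    """Category counts for one genotype, optionally with per-event records."""

    genotype: str
    counts: dict[str, int]
    records: list[MutationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("category counts must be non-negative")

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())


@dataclass
class RatePartition:
    """Per-category absolute and (optionally) relative mutation rates.

    A zero category count yields the one-pseudocount upper bound
    total_rate / n_total with ``bound_flag`` set.
    """

    genotype: str
    rates: dict[str, float]
    bound_flags: dict[str, bool]
    total_rate: float
    relative: dict[str, float] = field(default_factory=dict)

    def rounded(self, sig: int = 2) -> dict[str, float]:
        """Rates at reporting precision (2 significant figures by default)."""
        return {k: round_sig(v, sig) for k, v in self.rates.items()}


def scan_runs(sequence: str) -> tuple[tuple[int, int, str], ...]:
    """All maximal mononucleotide runs of length >= 2 as (start, length, base).

    Starts are 1-based; the returned tuples exactly tile every maximal run.
    """
    runs = []
    i = 0
    n = len(sequence)
    while i < n:
        j = i
        while j < n and sequence[j] == sequence[i]:
            j += 1
        if j - i >= 2:
            runs.append((i + 1, j - i, sequence[i]))
        i = j
    return tuple(runs)


def _check_ref(ref_seq: str, position: int, ref_allele: str) -> None:
    if not ref_allele:
        return
    end = position - 1 + len(ref_allele)
    if end > len(ref_seq) or ref_seq[position - 1 : end] != ref_allele:
        raise ValueError(
            f"ref allele {ref_allele!r} does not match reference at "
            f"position {position}"
        )


def _single_event_category(ref_allele: str, alt_allele: str) -> str:
    nref, nalt = len(ref_allele), len(alt_allele)
    if nref == 1 and nalt == 1:
        return "base substitution"
    if nref == 1 and nalt == 0:
        return "1-bp deletion"
    if nref == 0 and nalt == 1:
        return "1-bp insertion"
    # multi-bp indels, duplications, MNVs
    return "other"


def classify_mutation(
    ref_seq: str,
    position: int,
    ref_allele: str,
    alt_allele: str,
    neighbors: Iterable[int] = (),
    complex_window: int = DEFAULT_COMPLEX_WINDOW,
) -> str:
    """Spectrum category of one event given other event positions in the
    same isolate.

    Two or more events within ``complex_window`` bases of each other in one
    isolate are jointly a complex mutation; otherwise the category follows
    from the allele lengths alone.
    """
    _check_ref(ref_seq, position, ref_allele)
    if any(abs(p - position) <= complex_window for p in neighbors):
        return "complex"
    return _single_event_category(ref_allele, alt_allele)


def classify_isolate(
    ref_seq: str,
    events: Sequence[MutationRecord],
    complex_window: int = DEFAULT_COMPLEX_WINDOW,
) -> list[MutationRecord]:
    """Classify every event of one isolate, applying the complex-cluster rule.

    Order of the input events does not matter.
    """
    positions = [e.position for e in events]
    out = []
    for e in events:
        neighbors = [p for i, p in enumerate(positions) if events[i] is not e]
        cat = classify_mutation(
            ref_seq, e.position, e.ref_allele, e.alt_allele,
            neighbors, complex_window,
        )
        out.append(replace(e, category=cat))
    return out


def _run_at(ref_seq: str, position: int) -> int:
    """Length of the maximal run containing the reference base at position."""
    base = ref_seq[position - 1]
    i = position - 1
    while i > 0 and ref_seq[i - 1] == base:
        i -= 1
    j = position - 1
    n = len(ref_seq)
    while j + 1 < n and ref_seq[j + 1] == base:
        j += 1
    return j - i + 1


def _left_normalize_deletion(ref_seq: str, position: int) -> int:
    """Leftmost equivalent position for deleting ref_seq[position-1]."""
    base = ref_seq[position - 1]
    p = position
    while p > 1 and ref_seq[p - 2] == base:
        p -= 1
    return p


def annotate_run_context(
    ref_seq: str, record: MutationRecord
) -> MutationRecord:
    """Attach the mononucleotide-run length of the event site.

    1-bp indels are left-normalized first (shifted to the leftmost
    equivalent placement within a run of the deleted/inserted base), so
    every equivalent placement reports the same run length; substitutions
    get the run length of the reference base at their site.
    """
    if record.position > len(ref_seq) + (1 if record.ref_allele == "" else 0):
        raise ValueError("record position outside reference")
    pos = record.position
    if record.ref_allele and record.alt_allele:  # substitution / MNV
        _check_ref(ref_seq, pos, record.ref_allele)
        run_len = _run_at(ref_seq, pos)
        norm_pos = pos
    elif record.alt_allele == "":  # deletion
        _check_ref(ref_seq, pos, record.ref_allele)
        if len(record.ref_allele) == 1:
            norm_pos = _left_normalize_deletion(ref_seq, pos)
            run_len = _run_at(ref_seq, norm_pos)
        else:
            norm_pos = pos
            run_len = _run_at(ref_seq, pos)
    else:  # insertion before `pos`
        base = record.alt_allele[0]
        # find the maximal run of `base` touching any equivalent placement:
        # the insertion site can slide across an adjacent run of that base
        left = pos - 1  # 0-based index of the base before the gap
        right = pos - 1  # 0-based index of the base after the gap
        run_len = 1
        norm_pos = pos
        if len(record.alt_allele) == 1:
            # scan left from the gap
            i = left
            count = 0
            while i >= 1 and ref_seq[i - 1] == base:
                count += 1
                i -= 1
            # scan right from the gap
            j = right
            n = len(ref_seq)
            while j < n and ref_seq[j] == base:
                count += 1
                j += 1
            if count > 0:
                run_len = count
                norm_pos = i + 1
        else:
            run_len = 1
    return replace(record, run_length=run_len, position=norm_pos)


def fraction_in_runs(
    spectrum: MutationSpectrum, category: str, min_run: int
) -> float:
    """Fraction of a category's records inside runs of length >= min_run."""
    recs = [r for r in spectrum.records if r.category == category]
    if not recs:
        raise ValueError(f"no records of category {category!r}")
    if any(r.run_length is None for r in recs):
        raise ValueError("records lack run annotations")
    return sum(r.run_length >= min_run for r in recs) / len(recs)


def partition_rates(
    total_rate: float, spectrum: MutationSpectrum
) -> RatePartition:
    """Split a total mutation rate over categories by their spectrum share.

    per-category rate = total_rate * count / n_total.  A zero count gives
    the one-pseudocount upper bound total_rate * 1/n_total, flagged.
    """
    if total_rate <= 0:
        raise ValueError("total_rate must be positive")
    n = spectrum.n_total
    if n == 0:
        raise ValueError("empty spectrum")
    rates: dict[str, float] = {}
    flags: dict[str, bool] = {}
    for cat, count in spectrum.counts.items():
        if count > 0:
            rates[cat] = total_rate * count / n
            flags[cat] = False
        else:
            rates[cat] = total_rate / n
            flags[cat] = True
    return RatePartition(
        genotype=spectrum.genotype,
        rates=rates,
        bound_flags=flags,
        total_rate=total_rate,
    )


def relative_rates(
    partition: RatePartition, reference: RatePartition
) -> dict[str, float]:
    """Category-wise rate ratios against a reference genotype's partition.

    Includes a "total" entry.  A zero reference rate leaves that category
    out (undefined) with a warning.
    """
    out: dict[str, float] = {}
    for cat, rate in partition.rates.items():
        ref = reference.rates.get(cat)
        if ref is None or ref <= 0:
            warnings.warn(f"reference rate for {cat!r} is zero/missing; "
                          "relative rate undefined")
            continue
        out[cat] = rate / ref
    out["total"] = partition.total_rate / reference.total_rate
    return out


def repair_efficiency(
    mu_repair_proficient: float, mu_repair_deficient: float
) -> float:
    """Percent of replication errors removed by the repair pathway.

    efficiency (%) = 100 - 100 * (mu_proficient / mu_deficient): the share
    of the repair-deficient rate that the pathway eliminates.  Report
    rounded to the nearest integer; full precision is returned.
    """
    if mu_repair_deficient <= 0:
        raise ValueError("repair-deficient rate must be positive")
    if mu_repair_proficient < 0:
        raise ValueError("rates must be non-negative")
    if mu_repair_proficient > mu_repair_deficient:
        warnings.warn(
            "repair-proficient rate exceeds repair-deficient rate; "
            "negative efficiency"
        )
    return 100.0 - 100.0 * mu_repair_proficient / mu_repair_deficient
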