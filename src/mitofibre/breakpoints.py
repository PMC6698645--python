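"""Junction-repeat detection at mtDNA deletion breakpoints.

Many mtDNA deletions are flanked by short perfect direct repeats: the
retained 5' sequence ends with the same k-mer that begins the retained 3'
sequence, leaving one copy of the repeat at the rejoined junction. The
finder reports the longest such common suffix/prefix of the two retained
flanks; calls shorter than 3 bp are classed as "no repeat".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

#: Repeats shorter than this are reported as "no repeat".
MIN_REPEAT_BP = 3

_VALID = set("ACGT")


class FlankError(ValueError):
    pass


def _clean_flank(seq: str, label: str) -> str:
    s = seq.strip().upper()
    if not s:
        raise FlankError(f"{label}: empty flank sequence")
    for i, ch in enumerate(s):
        if ch not in _VALID:
            raise FlankError(
                f"{label}: invalid character {ch!r} at position {i + 1} "
                "(flanks must be A/C/G/T)"
            )
    return s


@dataclass(frozen=True)
class FlankPair:
    """Retained sequences ending at bp5 (5') and starting at bp3 (3')."""

    five_prime_flank: str
    three_prime_flank: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "five_prime_flank", _clean_flank(self.five_prime_flank, "5' flank")
        )
        object.__setattr__(
            self, "three_prime_flank", _clean_flank(self.three_prime_flank, "3' flank")
        )


@dataclass(frozen=True)
class RepeatCall:
    length_bp: int
    sequence: str
    klass: str


def classify_repeat(length_bp: int) -> str:
    """Class label for a repeat length; < 3 bp counts as no repeat."""
    if length_bp < 0:
        raise FlankError(f"negative repeat length {length_bp}")
    if length_bp < MIN_REPEAT_BP:
        return "no repeat"
    return f"{length_bp}bp perfect repeat"


def longest_junction_repeat(flanks: FlankPair) -> RepeatCall:
    """Longest perfect direct repeat at the junction.

    The repeat is the longest k such that the last k bases of the 5'
    retained flank equal the first k bases of the 3' retained flank.
    """
    f5, f3 = flanks.five_prime_flank, flanks.three_prime_flank
    best = 0
    for k in range(min(len(f5), len(f3)), 0, -1):
        if f5[-k:] == f3[:k]:
            best = k
            break
    seq = f5[-best:] if best else ""
    return RepeatCall(length_bp=best, sequence=seq, klass=classify_repeat(best))


def flanks_from_reference(
    reference: str, bp5: int, bp3: int, window: int = 30
) -> FlankPair:
    """Extract retained flanks around a deletion from a circular reference.

    ``reference`` is the full circular sequence (1-based coordinates);
    the 5' flank is the ``window`` bases ending at bp5 and the 3' flank
    the ``window`` bases starting at bp3, wrapping around the origin.
    """
    n = len(reference)
    if window < 1:
        raise FlankError(f"window must be >= 1, got {window}")
    if window > n:
        raise FlankError(f"window {window} exceeds reference length {n}")
    if not (1 <= bp5 <= n and 1 <= bp3 <= n):
        raise FlankError(f"breakpoints {bp5}/{bp3} outside 1..{n}")

    def circ(pos: int) -> str:  # 1-based circular indexing
        return reference[(pos - 1) % n]

    f5 = "".join(circ(p) for p in range(bp5 - window + 1, bp5 + 1))
    f3 = "".join(circ(p) for p in range(bp3, bp3 + window))
    return FlankPair(f5, f3)


def repeat_count_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Repeat-mediated deletion counts at the >=2 and >=3 bp thresholds.

    Published junction-repeat tallies vary in where they cut short
    repeats, so both counts are reported side by side rather than
    reconciled to any single printed figure.
    """
    total = len(calls)
    rows = []
    for cut in (2, 3):
        n = int((calls["repeat_length_bp"] >= cut).sum())
        rows.append(
            {
                "min_repeat_bp": cut,
                "n_repeat_mediated": n,
                "n_total": total,
                "percent": round(100 * n / total, 1) if total else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def read_reference_fasta(path: str | Path) -> str:
    """Read a single-record FASTA as an uppercase circular reference."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise FlankError(
            f"expected exactly one reference record, found {len(records)}"
        )
    return str(records[0].seq).upper()


def concordance(triplex_class: str | None, expected_class: str | None) -> str:
    """Compare the qPCR deletion class with the class expected from breakpoints."""
    if not triplex_class or not expected_class:
        return "incomparable"
    return "agree" if triplex_class == expected_class else "disagree"


def read_flank_table(path: str | Path) -> pd.DataFrame:
    """Read a flank CSV (product_id, five_prime_flank, three_prime_flank)."""
    df = pd.read_csv(path, dtype=str)
    need = {"product_id", "five_prime_flank", "three_prime_flank"}
    missing = need - set(df.columns)
    if missing:
        raise FlankError(f"flank table lacks columns: {sorted(missing)}")
    return df


def call_repeats(flank_table: pd.DataFrame) -> pd.DataFrame:
    """Run the repeat finder over a flank table; tidy calls out."""
    rows = []
    for r in flank_table.itertuples(index=False):
        call = longest_junction_repeat(
            FlankPair(r.five_prime_flank, r.three_prime_flank)
        )
        rows.append(
            {
                "product_id": r.product_id,
                "repeat_length_bp": call.length_bp,
                "repeat_sequence": call.sequence,
                "repeat_class": call.klass,
            }
        )
    return pd.DataFrame(rows)
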