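"""Phase-I post-processing: exclusion-list filtering with an audit trail.

Primary-screen hits include genes whose knockdown simply kills the cells
(any reporter collapses when the cell dies) and predicted-only ORFs. Both
are removed by subtracting named exclusion lists, in order, from the hit
list; the report records how many genes each list removed *from the running
survivor set*, so the per-list counts sum exactly to input − survivors.

Identifier matching is exact string match after whitespace trimming; no
synonym resolution is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field


@dataclass
class ExclusionReport:
    """Accounting of a sequential exclusion-filtering run."""

    input_count: int
    removed: dict[str, int] = field(default_factory=dict)
    survivors: list[str] = field(default_factory=list)

    @property
    def surviving_count(self) -> int:
        return len(self.survivors)

    def as_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "removed": dict(self.removed),
            "surviving_count": self.surviving_count,
            "survivors": list(self.survivors),
        }


def _clean(ids, what: str) -> list[str]:
    out = []
    for g in ids:
        g = str(g).strip()
        if not g:
            raise ValueError(f"empty gene identifier in {what}")
        out.append(g)
    return out


def apply_exclusions(hits, exclusion_lists: dict[str, set] | list[tuple[str, set]]
                     ) -> ExclusionReport:
    """Subtract named exclusion lists from a hit list, in order.

    Parameters
    ----------
    hits
        Gene identifiers from the upstream stage; duplicates are collapsed
        (first occurrence kept) with a warning. Input order is preserved in
        the survivors.
    exclusion_lists
        Ordered mapping name → iterable of gene ids. Later lists are counted
        against the survivors of earlier lists, so overlaps between lists
        are never double-counted.
    """
    hits = _clean(hits, "hit list")
    seen: dict[str, None] = {}
    for g in hits:
        if g in seen:
            warnings.warn(f"duplicate gene id {g!r} in hit list; collapsed",
                          stacklevel=2)
        seen[g] = None
    current = list(seen)
    report = ExclusionReport(input_count=len(current))
    items = (exclusion_lists.items() if isinstance(exclusion_lists, dict)
             else exclusion_lists)
    for name, excl in items:
        excl_list = _clean(excl, f"exclusion list {name!r}")
        excl_set = set(excl_list)
        if len(excl_set) < len(excl_list):
            warnings.warn(f"exclusion list {name!r} contains duplicates; "
                          "deduplicated", stacklevel=2)
        before = len(current)
        current = [g for g in current if g not in excl_set]
        report.removed[name] = before - len(current)
    report.survivors = current
    return report


def read_exclusion_list(path) -> list[str]:
    """Read a plain-text gene list: one id per line, ``#`` comments allowed."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out
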