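"""Step catalogs: the ordered vocabulary of surgical steps.

A catalog is the fixed list of ``(step_id, step_name)`` pairs against which
annotation events are validated and over which all cohort statistics are
indexed.  The built-in default is the 21-step robotic proctectomy catalog;
custom catalogs of any size >= 2 are accepted so the pipeline can be reused
for other procedures.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator


@dataclass(frozen=True)
class StepCatalog:
    """Ordered, immutable mapping of integer step ids to step names.

    Ids must be unique positive integers; at least two steps are required
    (a one-step catalog has no transitions to analyze).  Order is
    significant: reports and matrices follow catalog order.
    """

    entries: tuple[tuple[int, str], ...]
    _index: dict[int, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        entries = tuple((int(i), str(n)) for i, n in self.entries)
        object.__setattr__(self, "entries", entries)
        if len(entries) < 2:
            raise ValueError("a step catalog needs at least 2 steps")
        ids = [i for i, _ in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("step ids must be unique")
        if any(i <= 0 for i in ids):
            raise ValueError("step ids must be positive integers")
        names = [n for _, n in entries]
        if len(set(names)) != len(names):
            raise ValueError("step names must be unique")
        object.__setattr__(self, "_index", {i: k for k, (i, _) in enumerate(entries)})

    # -- mapping-style access -------------------------------------------------

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, step_id: int) -> bool:
        return step_id in self._index

    def __iter__(self) -> Iterator[tuple[int, str]]:
        return iter(self.entries)

    @property
    def step_ids(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.entries)

    @property
    def step_names(self) -> tuple[str, ...]:
        return tuple(n for _, n in self.entries)

    def name(self, step_id: int) -> str:
        return self.entries[self.index(step_id)][1]

    def index(self, step_id: int) -> int:
        """Position of ``step_id`` in catalog order (for matrix indexing)."""
        try:
            return self._index[step_id]
        except KeyError:
            raise KeyError(f"unknown step_id {step_id!r}") from None

    # -- io -------------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the catalog as two-column delimited text (step_id,step_name)."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["step_id", "step_name"])
            writer.writerows(self.entries)

    @classmethod
    def load(cls, path: str | Path) -> "StepCatalog":
        with open(path, newline="") as fh:
            sample = fh.readline()
            delim = "\t" if "\t" in sample else ","
            fh.seek(0)
            reader = csv.DictReader(fh, delimiter=delim)
            if reader.fieldnames is None or "step_id" not in reader.fieldnames:
                raise ValueError(f"{path}: expected a header with step_id,step_name")
            entries = [(int(row["step_id"]), row["step_name"]) for row in reader]
        return cls(tuple(entries))


#: The 21 steps of robotic proctectomy, in procedural report order.
PROCTECTOMY_STEPS: tuple[str, ...] = (
    "Initial Exposure",
    "IMA dissection",
    "Ligation & division of IMA",
    "IMV dissection",
    "Ligation & division of IMV",
    "Splenic flexure mobilization (medial-to-lateral)",
    "Splenic flexure mobilization (lateral-to-medial)",
    "Splenic flexure mobilization (supracolic)",
    "Rectal mobilization (medial-to-lateral)",
    "Descending & sigmoid colon mobilization (medial-to-lateral)",
    "Descending & sigmoid colon mobilization (lateral-to-medial)",
    "Posterior rectal dissection",
    "Anterior rectal dissection",
    "Right lateral rectal dissection",
    "Left lateral rectal dissection",
    "Division of the mesorectum",
    "Rectal transection",
    "Division of the mesocolon",
    "Proximal colon transection",
    "Testing for leak (optional)",
    "Colorectal anastomosis",
)


def default_catalog() -> StepCatalog:
    """The built-in 21-step robotic proctectomy catalog (ids 1..21)."""
    return StepCatalog(tuple((i + 1, name) for i, name in enumerate(PROCTECTOMY_STEPS)))
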