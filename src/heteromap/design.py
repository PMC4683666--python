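"""North Carolina II mating designs and partial cross schedules.

An NCII design mates ``a`` maternal lines with ``b`` paternal lines.  In a
*partial* design only a subset of the ``a*b`` factorial crosses is actually
made — the situation in hybrid breeding programs, where each sterile line is
crossed with a small number of restorer lines.  :func:`build_partial_ncii`
constructs the rotating cross schedule used throughout the simulation
experiments: maternal line ``i`` is mated to paternal lines
``i, i+1, ..., i+t-1`` (indices wrapped modulo ``b``), optionally padded with
a few extra wrapped crosses to reach a target population size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass


class DesignError(ValueError):
    """Raised for structurally invalid mating designs."""


@dataclass(frozen=True)
class MatingDesign:
    """Roster of maternal/paternal lines plus the explicit cross list.

    Maternal and paternal rosters are disjoint namespaces: reciprocal
    crosses are distinct and a label may not appear on both sides.
    """

    maternal_ids: tuple[str, ...]
    paternal_ids: tuple[str, ...]
    crosses: tuple[tuple[str, str], ...]
    t: int | None = None

    def __post_init__(self) -> None:
        mset, pset = set(self.maternal_ids), set(self.paternal_ids)
        if len(mset) != len(self.maternal_ids) or len(pset) != len(self.paternal_ids):
            raise DesignError("duplicate line labels in roster")
        if mset & pset:
            raise DesignError("maternal and paternal rosters must be disjoint")
        seen = set()
        for cross in self.crosses:
            m, p = cross
            if m not in mset:
                raise DesignError(f"cross references unknown maternal line {m!r}")
            if p not in pset:
                raise DesignError(f"cross references unknown paternal line {p!r}")
            if cross in seen:
                raise DesignError(f"duplicate cross {cross!r}")
            seen.add(cross)

    @property
    def a(self) -> int:
        return len(self.maternal_ids)

    @property
    def b(self) -> int:
        return len(self.paternal_ids)

    @property
    def n_crosses(self) -> int:
        return len(self.crosses)

    def cross_indices(self) -> tuple[list[int], list[int]]:
        """Row indices (maternal, paternal) of each cross in roster order."""
        mi = {m: i for i, m in enumerate(self.maternal_ids)}
        pi = {p: i for i, p in enumerate(self.paternal_ids)}
        return [mi[m] for m, _ in self.crosses], [pi[p] for _, p in self.crosses]

    def f1_ids(self) -> list[str]:
        return [f"{m}x{p}" for m, p in self.crosses]


def build_partial_ncii(
    a: int,
    b: int,
    t: int,
    extra: int = 0,
    maternal_prefix: str = "M",
    paternal_prefix: str = "P",
) -> MatingDesign:
    """Build the rotating partial NCII schedule.

    Parameters
    ----------
    a, b : int
        Number of maternal and paternal lines.
    t : int
        Crosses per maternal line (``1 <= t <= b``).  ``t == b`` yields the
        complete factorial.
    extra : int
        Number of padding crosses appended after the rotation, starting
        again from maternal line 1 with the next paternal offset and
        skipping any duplicates.
    """
    if a < 1 or b < 1:
        raise DesignError("a and b must be >= 1")
    if not 1 <= t <= b:
        raise DesignError(f"need 1 <= t <= b, got t={t}, b={b}")
    if extra < 0:
        raise DesignError("extra must be >= 0")
    if a * t + extra > a * b:
        raise DesignError("a*t + extra exceeds the full factorial; duplicates unavoidable")

    maternal = tuple(f"{maternal_prefix}{i + 1}" for i in range(a))
    paternal = tuple(f"{paternal_prefix}{j + 1}" for j in range(b))
    crosses: list[tuple[str, str]] = []
    seen: set[tuple[int, int]] = set()
    for i in range(a):
        for k in range(t):
            j = (i + k) % b
            crosses.append((maternal[i], paternal[j]))
            seen.add((i, j))
    added = 0
    for offset in itertools.count(t):
        if added == extra:
            break
        for i in range(a):
            if added == extra:
                break
            j = (i + offset) % b
            if (i, j) in seen:
                continue
            crosses.append((maternal[i], paternal[j]))
            seen.add((i, j))
            added += 1
    return MatingDesign(maternal, paternal, tuple(crosses), t=t)


def full_factorial(a: int, b: int, **kwargs) -> MatingDesign:
    """Complete ``a x b`` NCII cross set."""
    return build_partial_ncii(a, b, t=b, **kwargs)


def f1_proportion(design: MatingDesign) -> float:
    """Percentage of F1 hybrids among parents + F1s in the mapping population.

    Returns ``100 * n_crosses / (a + b + n_crosses)``.
    """
    if design.n_crosses == 0:
        raise DesignError("f1_proportion undefined for an empty design")
    n = design.n_crosses
    return 100.0 * n / (design.a + design.b + n)
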