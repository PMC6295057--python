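"""Closed-form bounds on the total number of upstream-region relations.

Before any terrain is processed, the total size of the upstream table for n
regions can be bracketed by two thought experiments:

* **Maximum** — all n regions sit on one linear river, one after another,
  so region k (counting from the headwater) has k-1 regions upstream. The
  total is the arithmetic series 0 + 1 + ... + (n-1) = n(n-1)/2 under the
  *exclusive* convention (a region is not its own upstream neighbor), or
  1 + 2 + ... + n = n(n+1)/2 under the *inclusive* convention in which each
  region is also counted once for itself. The published headline bounds for
  this tool's original national use case follow the inclusive convention,
  which is therefore the default here; the upstream table itself is
  exclusive. The two differ by exactly n.
* **Minimum** — every region sits on its own small river with nothing above
  it (shoreline villages around a conical island): each region contributes
  only itself, so the total over survey years is simply the sum of the
  yearly region counts.

All arithmetic is exact Python integers (the national-scale values exceed
32-bit range).
"""

from __future__ import annotations

from .errors import EmptyInputError, ParameterError

CONVENTIONS = ("inclusive", "exclusive")


def theoretical_max(n: int, convention: str = "inclusive") -> int:
    """Largest possible relation count for n regions on a single linear river.

    ``inclusive`` counts each region once for itself (n(n+1)/2);
    ``exclusive`` counts only strictly-upstream neighbors (n(n-1)/2).
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if convention not in CONVENTIONS:
        raise ParameterError(f"convention must be one of {CONVENTIONS}")
    if convention == "inclusive":
        return n * (n + 1) // 2
    return n * (n - 1) // 2


def theoretical_min(village_counts: list[int]) -> int:
    """Smallest possible total over survey years: the sum of the counts
    (each region counted once, with no upstream neighbors)."""
    if not village_counts:
        raise EmptyInputError("village_counts must not be empty")
    for n in village_counts:
        if n < 1:
            raise ParameterError(f"every count must be >= 1, got {n}")
    return sum(village_counts)


def pixels_scanned(terrestrial_pixels: int, n_years: int) -> int:
    """Total number of drainage pixels examined across repeated survey years:
    the DEM's terrestrial pixel count times the number of years."""
    if terrestrial_pixels < 1 or n_years < 1:
        raise ParameterError("terrestrial_pixels and n_years must be >= 1")
    return terrestrial_pixels * n_years
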