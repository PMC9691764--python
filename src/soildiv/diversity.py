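"""Per-quadrat species diversity indices.

For a quadrat with ``S`` species of relative abundance ``P_i``:

* Shannon-Wiener  ``H' = -sum P_i ln P_i``  (nats)
* Simpson         ``D  = 1 - sum P_i**2``
* Pielou evenness ``J  = H' / ln S``

Natural logarithms throughout.  Species with zero count in a quadrat are
excluded from ``S`` and the sums.  A monoculture has ``H' = 0`` and
``D = 0`` and undefined ``J`` (NaN); an all-zero quadrat is flagged and gets
NaN for every index rather than zeros, since "no individuals" is missing
information, not zero diversity.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["diversity_indices", "species_columns"]


def species_columns(table: pd.DataFrame) -> list[str]:
    """Columns of ``table`` holding species abundances (``sp_*`` prefix)."""
    return [c for c in table.columns if c.startswith("sp_")]


def diversity_indices(table: pd.DataFrame, species: list[str] | None = None) -> pd.DataFrame:
    """Compute S, Shannon H', Simpson D and Pielou J for every quadrat.

    Parameters
    ----------
    table
        Quadrat table with a species abundance block (non-negative counts).
        ``quadrat_id``, ``x`` and ``y`` columns are carried through when
        present.
    species
        Names of the abundance columns; defaults to all ``sp_*`` columns.

    Returns
    -------
    DataFrame with columns ``quadrat_id, x, y, S, shannon, simpson, pielou``.
    Quadrats with no individuals are counted in ``result.attrs["n_empty"]``
    and quadrats with a single species in ``result.attrs["n_monoculture"]``
    (their Pielou index is NaN).
    """
    species = species_columns(table) if species is None else list(species)
    if not species:
        raise ValueError("no species abundance columns found")
    counts = table[species].to_numpy(dtype=float)
    if np.any(counts < 0) or np.any(~np.isfinite(counts)):
        raise ValueError("abundances must be finite and non-negative")

    totals = counts.sum(axis=1)
    richness = (counts > 0).sum(axis=1)
    empty = totals == 0

    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals[:, None]
        plogp = np.where(counts > 0, p * np.log(p), 0.0)
        shannon = -plogp.sum(axis=1) + 0.0  # avoid -0.0 in monocultures
        simpson = 1.0 - np.where(counts > 0, p**2, 0.0).sum(axis=1)
        pielou = np.where(richness >= 2, shannon / np.log(np.maximum(richness, 2)), np.nan)

    shannon = np.where(empty, np.nan, shannon)
    simpson = np.where(empty, np.nan, simpson)
    pielou = np.where(empty, np.nan, pielou)

    out = pd.DataFrame(
        {"S": richness, "shannon": shannon, "simpson": simpson, "pielou": pielou}
    )
    for col in ("y", "x", "quadrat_id"):
        if col in table.columns:
            out.insert(0, col, table[col].to_numpy())
    out.attrs["n_empty"] = int(empty.sum())
    out.attrs["n_monoculture"] = int((richness == 1).sum())
    if out.attrs["n_empty"]:
        log.warning("%d quadrats contain no individuals; indices set to NaN",
                    out.attrs["n_empty"])
    if out.attrs["n_monoculture"]:
        log.info("%d monoculture quadrats; Pielou evenness undefined there",
                 out.attrs["n_monoculture"])
    return out
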