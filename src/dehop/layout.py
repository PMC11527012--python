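"""Dual-index plate topology: hop-potential classification.

In a pooled dual-indexed plate, a free i7 primer can re-label a
fragment from any well in the same plate row and a free i5 primer from
any well in the same column.  A recipient well can therefore acquire
reads from a donor cell type through zero, one, or both index sides;
we classify each recipient against a donor type as ``dual``,
``i7_only``, ``i5_only`` or ``none``.  Classification is within each
pool only: index sets are reused across independently sequenced pools.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import ValidationError, WellTable

HOP_CLASSES = ("dual", "i7_only", "i5_only", "none")


@dataclass
class HopPotential:
    recipient_cell: str
    donor_type: str
    hop_class: str
    n_i7_donors: int
    n_i5_donors: int


def _classify(n_i7: int, n_i5: int) -> str:
    if n_i7 > 0 and n_i5 > 0:
        return "dual"
    if n_i7 > 0:
        return "i7_only"
    if n_i5 > 0:
        return "i5_only"
    return "none"


def classify_hop_potential(wells: WellTable, donor_type) -> list[HopPotential]:
    """One :class:`HopPotential` per recipient well (cell or empty).

    Donors are wells with ``status == 'cell'`` and the given type, in
    the recipient's own pool; a recipient is never its own donor.
    Empty wells are valid recipients (pure contamination sensors) but
    never donors; qc_fail wells are neither.
    """
    df = wells.frame
    donors = df[(df["status"] == "cell") & (df["cell_type"] == donor_type)]
    if donors.empty:
        raise ValidationError(f"unknown or absent donor cell type {donor_type!r}")
    out: list[HopPotential] = []
    recipients = df[df["status"].isin(("cell", "empty"))]
    for pool, pool_recipients in recipients.groupby("pool_id", sort=False):
        pool_donors = donors[donors["pool_id"] == pool]
        i7_counts = pool_donors["i7_index"].value_counts()
        i5_counts = pool_donors["i5_index"].value_counts()
        donor_ids = set(pool_donors["cell_id"])
        for row in pool_recipients.itertuples(index=False):
            n_i7 = int(i7_counts.get(row.i7_index, 0))
            n_i5 = int(i5_counts.get(row.i5_index, 0))
            if row.cell_id in donor_ids:
                # exclude the recipient itself; it shares both of its own indexes
                n_i7 -= 1
                n_i5 -= 1
            out.append(
                HopPotential(row.cell_id, donor_type, _classify(n_i7, n_i5), n_i7, n_i5)
            )
    return out


def group_recipients_by_class(potentials: list[HopPotential]) -> dict[str, list[str]]:
    """Partition recipients by hop class; classes may be empty."""
    donor_types = {p.donor_type for p in potentials}
    if len(donor_types) > 1:
        raise ValidationError(f"mixed donor types in potentials: {sorted(donor_types)}")
    groups: dict[str, list[str]] = {c: [] for c in HOP_CLASSES}
    for p in potentials:
        groups[p.hop_class].append(p.recipient_cell)
    return groups


def potentials_frame(potentials: list[HopPotential]) -> pd.DataFrame:
    """TSV-ready table: cell_id, donor_type, class, n_i7_donors, n_i5_donors."""
    return pd.DataFrame(
        {
            "cell_id": [p.recipient_cell for p in potentials],
            "donor_type": [p.donor_type for p in potentials],
            "class": [p.hop_class for p in potentials],
            "n_i7_donors": [p.n_i7_donors for p in potentials],
            "n_i5_donors": [p.n_i5_donors for p in potentials],
        }
    )
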