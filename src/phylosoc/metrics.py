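"""Per-species social-structure statistics.

Three quantities summarise the reproductive structure of a social group
with B breeding females out of N total females:

* the proportion of breeders, ``P = B / N``;
* the monopolization-of-breeding-positions index,
  ``M = (1 - B/N) / (1 - 1/N)``, which rescales 1 - P by the maximum
  skew attainable at that group size so that M = 1 whenever a single
  female monopolizes breeding (B = 1) regardless of N, and M = 0 when
  breeding is shared equitably by all females (B = N);
* the social category: ``single_breeder`` (monogyny in insects,
  singular breeding in vertebrates) when the species mean is one
  breeding female per group, ``multi_breeder`` (polygyny / plural
  breeding) when it exceeds one.

M is undefined at N <= 1 (its denominator vanishes); callers must
exclude such records explicitly.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .data import Dataset

#: default tolerance for treating a mean of "one breeding female" as exactly one
CLASSIFICATION_TOLERANCE = 1e-9

SINGLE_BREEDER = "single_breeder"
MULTI_BREEDER = "multi_breeder"

METRIC_COLUMNS = (
    "species_id",
    "taxon_group",
    "B",
    "N",
    "proportion_breeders",
    "monopolization",
    "social_category",
)


def proportion_breeders(B: float, N: float) -> float:
    """Proportion of breeding females, B/N, for 0 < B <= N."""
    if not (B > 0 and N > 0):
        raise ValueError(f"B and N must be positive (got B={B}, N={N})")
    if B > N:
        raise ValueError(f"breeding females B={B} cannot exceed total females N={N}")
    return B / N


def monopolization_index(B: float, N: float) -> float:
    """Degree of monopolization of breeding positions, (1 - B/N)/(1 - 1/N).

    Ranges over [0, 1]: 1 when breeding is limited to a single female
    (B = 1), 0 when it is shared equitably among all females (B = N).
    Defined only for N > 1 and 1 <= B <= N.
    """
    if N <= 1:
        raise ValueError(
            f"monopolization index undefined for N <= 1 (got N={N}): "
            "denominator 1 - 1/N vanishes"
        )
    if B < 1:
        raise ValueError(f"B must be >= 1 (got B={B})")
    if B > N:
        raise ValueError(f"breeding females B={B} cannot exceed total females N={N}")
    return (1.0 - B / N) / (1.0 - 1.0 / N)


def classify_social_structure(
    B: float, tolerance: float = CLASSIFICATION_TOLERANCE
) -> str:
    """Classify by the mean number of breeding females per group.

    ``single_breeder`` when |B - 1| <= tolerance, ``multi_breeder`` when
    B > 1 + tolerance.  B depends on the breeders only, never on group
    size.
    """
    if B < 1.0 - tolerance:
        raise ValueError(
            f"cannot classify B={B}: a mature group holds at least one breeder on average"
        )
    return SINGLE_BREEDER if B <= 1.0 + tolerance else MULTI_BREEDER


def compute_metrics(
    ds: "Dataset", tolerance: float = CLASSIFICATION_TOLERANCE
) -> pd.DataFrame:
    """Per-species metric table.

    The monopolization column is NaN for records with N <= 1 (index
    undefined); such rows are flagged via :func:`taxon_summary` and must
    be excluded from index summaries.
    """
    rows = []
    for rec in ds:
        b, n = rec.mean_breeding_females, rec.mean_total_females
        mono = monopolization_index(b, n) if n > 1 and b >= 1 else np.nan
        cat = rec.social_category
        if cat is None and b >= 1.0 - tolerance:
            cat = classify_social_structure(b, tolerance)
        rows.append(
            {
                "species_id": rec.species_id,
                "taxon_group": rec.taxon_group,
                "B": b,
                "N": n,
                "proportion_breeders": proportion_breeders(b, n),
                "monopolization": mono,
                "social_category": cat,
            }
        )
    return pd.DataFrame(rows, columns=list(METRIC_COLUMNS))


def taxon_summary(
    ds: "Dataset",
    taxa: Iterable[str] | None = None,
    tolerance: float = CLASSIFICATION_TOLERANCE,
) -> pd.DataFrame:
    """Per-taxon summary of counts and index / group-size extrema.

    Records with N <= 1 are excluded from the extrema and counted in
    ``n_excluded``.  Taxa listed in ``taxa`` but absent from the data
    appear with ``n_species = 0`` and NaN extrema rather than being
    silently omitted.
    """
    metrics = compute_metrics(ds, tolerance)
    if taxa is None:
        taxa = list(dict.fromkeys(metrics["taxon_group"]))
    rows = []
    for taxon in taxa:
        sub = metrics[metrics["taxon_group"] == taxon]
        included = sub[sub["N"] > 1]
        rows.append(
            {
                "taxon_group": taxon,
                "n_species": len(sub),
                "n_multi_breeder": int((sub["social_category"] == MULTI_BREEDER).sum()),
                "n_excluded": len(sub) - len(included),
                "monopolization_min": included["monopolization"].min(),
                "monopolization_max": included["monopolization"].max(),
                "total_females_min": included["N"].min() if len(included) else np.nan,
                "total_females_max": included["N"].max() if len(included) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("taxon_group")


def write_metric_table(metrics: pd.DataFrame, path) -> None:
    """Write the per-species metric table as TSV."""
    metrics.to_csv(path, sep="\t", index=False, float_format="%.12g")
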