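"""The 11-species beta-globin first-exon benchmark.

The standard benchmark in the graphical-representation literature: the first
exons of the beta-globin gene of 11 species (GenBank accessions below; the
exon subsequences themselves must be supplied by the user as FASTA — this
package does not fetch or slice GenBank records). The reference 4-D
descriptors and the reference pairwise similarity-distance matrix published
for this benchmark under the massive-point spiral method (L = 86,
epsilon = 0.0375) are bundled here, both as inputs for distance-only runs and
as the ground truth for the package's own regression tests.

The published account does not record the functional form of the post-L mass
restraint, only its scale; `screen_restraint_variants` therefore runs a
user-supplied exon FASTA through every restraint/centroid variant combination
and reports which one, if any, reproduces the reference descriptors.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .descriptor import DESCRIPTOR_COLUMNS, descriptor_table
from .sequence_io import NucleotideSequence
from .spiral import COM_VARIANTS, RESTRAINT_VARIANTS, RepresentationParams
from skbio import DistanceMatrix

#: Species label -> GenBank accession of the gene whose first exon is used.
BETA_GLOBIN_ACCESSIONS = {
    "Human": "U01317",
    "Gorilla": "X61109",
    "Chimpanzee": "X02345",
    "Rat": "X06701",
    "Mouse": "V00722",
    "Lemur": "M15734",
    "Rabbit": "V00882",
    "Goat": "M15387",
    "Bovine": "X00376",
    "Opossum": "J03643",
    "Gallus": "V00409",
}

BETA_GLOBIN_SPECIES = tuple(BETA_GLOBIN_ACCESSIONS)

#: First-exon lengths (nt); the shortest (86) is the conventional reference
#: length L for this benchmark.
BETA_GLOBIN_EXON_LENGTHS = {
    "Human": 92, "Gorilla": 93, "Chimpanzee": 105, "Rat": 92, "Mouse": 93,
    "Lemur": 92, "Rabbit": 92, "Goat": 86, "Bovine": 86, "Opossum": 92,
    "Gallus": 92,
}

BENCHMARK_L = 86
BENCHMARK_EPSILON = 0.0375

# Reference descriptors [r_A, r_C, r_G, r_T] as published for this benchmark
# (4 decimal places).
_REFERENCE_DESCRIPTORS = {
    "Human":      (1.6674, 1.7921, 1.7233, 1.7689),
    "Gorilla":    (1.6674, 1.7921, 1.7233, 1.7727),
    "Chimpanzee": (1.6885, 1.8085, 1.7239, 1.7845),
    "Rat":        (1.6074, 1.7858, 1.8242, 1.7462),
    "Mouse":      (1.5943, 1.7480, 1.8407, 1.7921),
    "Lemur":      (1.6781, 1.6659, 1.8149, 1.8046),
    "Rabbit":     (1.6454, 1.7145, 1.8690, 1.7809),
    "Goat":       (1.5416, 1.6808, 1.8246, 1.8476),
    "Bovine":     (1.5416, 1.5929, 1.8056, 1.8471),
    "Opossum":    (1.5693, 1.6713, 1.9416, 1.7398),
    "Gallus":     (1.7986, 1.6879, 1.9639, 1.7140),
}

# Reference pairwise similarity distances as published (4 decimal places),
# row order = BETA_GLOBIN_SPECIES.
_REFERENCE_DISTANCES = """
0      0.0038 0.0309 0.1198 0.1470 0.1604 0.1670 0.2114 0.2616 0.2696 0.2983
0.0038 0      0.0292 0.1206 0.1465 0.1596 0.1668 0.2100 0.2604 0.2701 0.2991
0.0309 0.0292 0      0.1365 0.1620 0.1707 0.1782 0.2281 0.2804 0.2870 0.2988
0.1198 0.1206 0.1365 0      0.0631 0.1513 0.0987 0.1602 0.2282 0.1684 0.2583
0.1470 0.1465 0.1620 0.0631 0      0.1208 0.0683 0.1031 0.1763 0.1393 0.2582
0.1604 0.1596 0.1707 0.1513 0.1208 0      0.0832 0.1443 0.1608 0.1792 0.2131
0.1670 0.1668 0.1782 0.0987 0.0683 0.0832 0      0.1355 0.1844 0.1209 0.1940
0.2114 0.2100 0.2281 0.1602 0.1031 0.1443 0.1355 0      0.0900 0.1618 0.3215
0.2616 0.2604 0.2804 0.2282 0.1763 0.1608 0.1844 0.0900 0      0.1921 0.3433
0.2696 0.2701 0.2870 0.1684 0.1393 0.1792 0.1209 0.1618 0.1921 0      0.2324
0.2983 0.2991 0.2988 0.2583 0.2582 0.2131 0.1940 0.3215 0.3433 0.2324 0
"""


def reference_descriptors() -> pd.DataFrame:
    """Published benchmark descriptors, indexed by species, columns r_A..r_T."""
    return pd.DataFrame.from_dict(
        _REFERENCE_DESCRIPTORS, orient="index", columns=list(DESCRIPTOR_COLUMNS)
    )


def reference_distance_matrix() -> DistanceMatrix:
    """Published benchmark similarity-distance matrix (4-decimal precision)."""
    rows = [
        [float(x) for x in line.split()]
        for line in _REFERENCE_DISTANCES.strip().splitlines()
    ]
    return DistanceMatrix(np.array(rows), ids=list(BETA_GLOBIN_SPECIES))


def screen_restraint_variants(
    seqs: Sequence[NucleotideSequence],
    reference: pd.DataFrame | None = None,
    L: int = BENCHMARK_L,
    epsilon: float = BENCHMARK_EPSILON,
    atol: float = 1e-4,
) -> pd.DataFrame:
    """Run every restraint/centroid variant and compare against reference descriptors.

    For each (restraint_variant, com_variant) pair, the descriptors of
    ``seqs`` are computed under (L, epsilon) and compared row-by-row against
    ``reference`` (indexed by sequence id, columns r_A..r_T; defaults to the
    bundled benchmark values). Returns one row per combination with the
    maximum absolute componentwise deviation and whether every component
    agrees within ``atol`` (half a unit of the reference's printed 4-decimal
    precision by default is 5e-5; the default 1e-4 allows one printed ulp).

    Sequences whose ids are missing from the reference index are ignored; at
    least one id must match.
    """
    if reference is None:
        reference = reference_descriptors()
    ids = [s.id for s in seqs if s.id in reference.index]
    if not ids:
        raise ValueError("no sequence id matches the reference index")
    kept = [s for s in seqs if s.id in reference.index]
    rows = []
    for restraint in RESTRAINT_VARIANTS:
        for com in COM_VARIANTS:
            params = RepresentationParams(
                L=L, epsilon=epsilon, restraint_variant=restraint, com_variant=com
            )
            table = descriptor_table(kept, params).set_index("id")
            dev = (
                table[list(DESCRIPTOR_COLUMNS)] - reference.loc[ids, list(DESCRIPTOR_COLUMNS)]
            ).abs()
            rows.append(
                {
                    "restraint_variant": restraint,
                    "com_variant": com,
                    "max_abs_deviation": float(dev.to_numpy().max()),
                    "matches_reference": bool((dev.to_numpy() <= atol).all()),
                    "n_sequences": len(kept),
                }
            )
    return pd.DataFrame(rows)
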