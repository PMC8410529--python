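"""Shared vocabulary and containers for the CTC analysis pipeline.

Channel roles name the five fluorescence channels of the assay panel:
a nuclear stain, the renal marker CAXII, pan-cytokeratin (CK), a pooled
white-blood-cell/endothelial exclusion channel (CD34/CD45/CD66b on one
dye), and one checkpoint/antigen-presentation biomarker channel (PD-L1
or HLA-I).  Phenotype labels partition every segmented cell: cells
positive on the exclusion channel are EXCLUDED outright; the remaining
cells are CTC subtypes (CAXII single-positive, double-positive, CK
single-positive) or TRIPLE_NEG, which is never counted as a CTC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Channel roles (order is the canonical page order in multichannel TIFFs).
NUCLEAR = "nuclear"
CAXII = "caxii"
CK = "ck"
EXCLUSION = "exclusion"
BIOMARKER = "biomarker"
CHANNEL_ROLES: tuple[str, ...] = (NUCLEAR, CAXII, CK, EXCLUSION, BIOMARKER)

# Marker channels quantified per cell (everything but the nuclear stain).
MARKER_ROLES: tuple[str, ...] = (CAXII, CK, EXCLUSION, BIOMARKER)

# Phenotype labels.
LABEL_EXCLUDED = "EXCLUDED"
LABEL_CAXII_S = "CAXII_S"
LABEL_DP = "DP"
LABEL_CK_S = "CK_S"
LABEL_TRIPLE_NEG = "TRIPLE_NEG"
LABEL_WBC = "WBC"  # synthetic ground-truth alias for exclusion-positive cells

PHENOTYPE_LABELS: tuple[str, ...] = (
    LABEL_EXCLUDED,
    LABEL_CAXII_S,
    LABEL_DP,
    LABEL_CK_S,
    LABEL_TRIPLE_NEG,
)

# CTC subtypes (countable phenotypes) and reporting subpopulations.
CTC_LABELS: tuple[str, ...] = (LABEL_CAXII_S, LABEL_DP, LABEL_CK_S)
SUBPOP_ALL_CTC = "ALL_CTC"
SUBPOP_CK_PLUS = "CK_PLUS"  # CK_S union DP
SUBPOPULATIONS: tuple[str, ...] = (
    SUBPOP_ALL_CTC,
    LABEL_CAXII_S,
    LABEL_DP,
    LABEL_CK_S,
    SUBPOP_CK_PLUS,
)

TRUTH_PREFIX = "truth_"


def raw_col(role: str) -> str:
    """Column name for the raw mean intensity of a channel role."""
    return f"raw_{role}"


def bgsub_col(role: str) -> str:
    """Column name for the background-subtracted mean intensity of a role."""
    return f"bgsub_{role}"


def truth_columns(columns) -> list[str]:
    """Return the ground-truth columns present in a table's columns."""
    return [c for c in columns if c.startswith(TRUTH_PREFIX)]


def strip_truth(table):
    """Drop generator ground-truth columns from a cell table.

    Analysis stages must never read ``truth_*`` columns; stripping them
    is a no-op on real data and a schema guarantee on synthetic data.
    """
    return table.drop(columns=truth_columns(table.columns))


@dataclass
class ChannelStack:
    """One imaging field: a 2-D intensity array per channel role.

    Parameters
    ----------
    channels
        Mapping from channel role (see :data:`CHANNEL_ROLES`) to a 2-D
        float array in arbitrary fluorescence units.  All arrays must
        share one shape; pixel coordinates are 0-based ``(row, col)``.
    """

    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = set()
        for role, img in self.channels.items():
            img = np.asarray(img, dtype=float)
            if img.ndim != 2:
                raise ValueError(f"channel {role!r} is not a 2-D image")
            self.channels[role] = img
            shapes.add(img.shape)
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.shape

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def __getitem__(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise KeyError(
                f"channel role {role!r} missing (present: {sorted(self.channels)})"
            ) from None

    def __contains__(self, role: str) -> bool:
        return role in self.channels

    def map(self, fn) -> "ChannelStack":
        """Apply ``fn`` to every channel image, returning a new stack."""
        return ChannelStack({role: fn(img) for role, img in self.channels.items()})
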