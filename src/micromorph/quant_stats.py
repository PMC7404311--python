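"""Non-image support computations: ddCT relative expression and blot load normalisation.

Relative mRNA quantification uses the ddCT method with an assumed
amplification efficiency of 2: expression ratio = 2^(−ΔΔCT), where ΔCT is the
target CT minus the reference level of each sample.  The reference level is
the geometric mean of three reference genes, chosen from four candidates by a
stability ranking (lowest average cross-sample variability of pairwise CT
differences); the chosen subset is always reported.

Immunoblot target bands are normalised by the geometric mean of two loading
controls (vinculin and myosin IIa).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionResult:
    """ddCT outcome for one target gene."""

    target: str
    references_used: tuple[str, ...]
    dct_treated: float
    dct_control: float
    ddct: float
    relative_expression: float  # 2^(-ddCT)
    reference_stability: dict  # gene -> stability score (lower = more stable)


@dataclass
class BlotResult:
    """Loading-normalised immunoblot quantification."""

    normalized: dict  # lane -> target / geometric_mean(controls)
    ratio_treated_control: float
    controls: tuple[str, ...]


def _ct_matrix(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Mean CT per (gene, sample), averaging technical replicates."""
    required = {"sample", "gene", "ct"}
    if not required <= set(ct_table.columns):
        raise ValueError(f"CT table needs columns {sorted(required)}")
    if not np.isfinite(ct_table["ct"]).all():
        raise ValueError("non-finite CT value")
    return ct_table.pivot_table(index="gene", columns="sample", values="ct", aggfunc="mean")


def _reference_stability(cts: pd.DataFrame, refs: list[str]) -> dict[str, float]:
    """Stability score per reference gene: mean cross-sample SD of pairwise ΔCTs.

    For each pair of references the CT difference should be constant across
    samples if both are stable; a gene whose pairwise differences vary is
    penalised (the geNorm idea, reduced to its ranking step).
    """
    scores = {}
    for g in refs:
        sds = [
            float((cts.loc[g] - cts.loc[h]).std(ddof=0))
            for h in refs
            if h != g
        ]
        scores[g] = float(np.mean(sds))
    return scores


def ddct(
    ct_table: pd.DataFrame,
    target_gene: str = "Pkhd1",
    reference_genes: list[str] | None = None,
    treated: str = "treated",
    control: str = "control",
    n_references_used: int = 3,
) -> ExpressionResult:
    """Relative expression of ``target_gene`` (treated vs control) by ddCT.

    ``ct_table`` is tidy: columns ``sample``, ``gene``, ``ct`` (plus anything
    else, ignored); technical replicates are averaged.  Of the candidate
    reference genes the ``n_references_used`` most stable are kept; using the
    arithmetic mean of their CTs is equivalent to the geometric mean of their
    expression levels.
    """
    cts = _ct_matrix(ct_table)
    for s in (treated, control):
        if s not in cts.columns:
            raise ValueError(f"sample {s!r} not in table")
    if reference_genes is None:
        reference_genes = [g for g in cts.index if g != target_gene]
    if target_gene not in cts.index:
        raise ValueError(f"target {target_gene!r} not in table")
    usable = [g for g in reference_genes if np.isfinite(cts.loc[g, [treated, control]]).all()]
    if len(usable) < n_references_used:
        raise ValueError(
            f"need at least {n_references_used} usable reference genes, have {len(usable)}"
        )

    stability = _reference_stability(cts, usable)
    chosen = tuple(sorted(usable, key=lambda g: stability[g])[:n_references_used])

    ref_ct = cts.loc[list(chosen)].mean(axis=0)  # arithmetic mean of CTs == geometric mean level
    dct = cts.loc[target_gene] - ref_ct
    ddct_val = float(dct[treated] - dct[control])
    return ExpressionResult(
        target=target_gene,
        references_used=chosen,
        dct_treated=float(dct[treated]),
        dct_control=float(dct[control]),
        ddct=ddct_val,
        relative_expression=float(2.0 ** (-ddct_val)),
        reference_stability=stability,
    )


def blot_normalize(
    bands: pd.DataFrame,
    target: str = "target",
    controls: tuple[str, str] = ("vinculin", "myosin"),
    treated: str = "treated",
    control_lane: str = "control",
) -> BlotResult:
    """Normalise target band intensities by the geometric mean of loading controls.

    ``bands`` is tidy: columns ``lane``, ``band``, ``intensity``.  The
    normalised value per lane is target / sqrt(control1 × control2); the
    treated/control ratio of normalised values is reported.
    """
    required = {"lane", "band", "intensity"}
    if not required <= set(bands.columns):
        raise ValueError(f"band table needs columns {sorted(required)}")
    if (bands["intensity"] <= 0).any():
        raise ValueError("band intensities must be > 0")
    mat = bands.pivot_table(index="band", columns="lane", values="intensity", aggfunc="mean")
    for b in (target, *controls):
        if b not in mat.index:
            raise ValueError(f"band {b!r} missing")
    norm = {}
    for lane in mat.columns:
        geo = float(np.sqrt(mat.loc[controls[0], lane] * mat.loc[controls[1], lane]))
        norm[lane] = float(mat.loc[target, lane] / geo)
    if treated not in norm or control_lane not in norm:
        raise ValueError(f"lanes {treated!r} and {control_lane!r} required for the ratio")
    return BlotResult(
        normalized=norm,
        ratio_treated_control=norm[treated] / norm[control_lane],
        controls=controls,
    )
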