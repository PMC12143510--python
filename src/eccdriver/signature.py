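"""The 17-gene prognostic risk score over z-normalized expression.

The packaged model is a fixed linear combination of 17 genes selected from
the common eccDNA-driven genes on chromosome 11q13 (univariate Cox screen,
LASSO at the one-SE lambda, multivariate Cox with stepwise selection — the
fitting itself is upstream work and not part of this package; only the
fitted coefficients are shipped). Expression is z-scored per gene across
samples, each sample's score is the coefficient-weighted sum, and the
cohort median splits samples into high- and low-risk groups.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import SignatureModel

logger = logging.getLogger(__name__)

# Published 17-gene risk model; gene tokens kept verbatim from the source
# model. Two tokens are older aliases of current HGNC symbols (see
# SYMBOL_ALIASES); which annotation vintage applies to a given expression
# matrix is the caller's concern.
CEDG17_COEFFICIENTS = (
    ("C11orf24", 0.2768),
    ("MYEOV", 0.0661),
    ("ALDH3B1", 0.0843),
    ("UNC93B1", 0.1076),
    ("MRGPRD", 0.1479),
    ("PPFIA1", 0.2884),
    ("FGF19", 0.0353),
    ("GAL", 0.0235),
    ("ANKRD13D", 0.0861),
    ("FGF3", 0.0272),
    ("MRPL21", 0.0658),
    ("MTL5", -0.1364),
    ("CHKA", -0.1131),
    ("TCIRG1", -0.0844),
    ("CCND1", -0.1363),
    ("IGHMBP2", -0.1111),
    ("SAPS3", -0.1099),
)

# older token -> current HGNC symbol
SYMBOL_ALIASES = {"MTL5": "TESMIN", "SAPS3": "PPP6R3"}

CEDG17 = SignatureModel(
    genes=tuple(g for g, _ in CEDG17_COEFFICIENTS),
    coefficients=tuple(c for _, c in CEDG17_COEFFICIENTS),
    name="cedg17",
    normalization="zscore",
)


def load_model(spec: str) -> SignatureModel:
    """Resolve ``builtin:cedg17`` or a two-column ``gene\\tcoefficient`` TSV."""
    if spec == "builtin:cedg17":
        return CEDG17
    df = pd.read_csv(spec, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{spec}: model file needs gene and coefficient columns")
    genes = tuple(df.iloc[:, 0].astype(str))
    coefs = tuple(df.iloc[:, 1].astype(float))
    return SignatureModel(genes=genes, coefficients=coefs, name=str(spec))


def zscore(expr: pd.DataFrame, center_only: bool = False) -> pd.DataFrame:
    """Zero-mean normalize each gene (row) across samples.

    Default divides by the population standard deviation (ddof=0); with
    ``center_only`` the rows are mean-centered without scaling. Constant
    rows map to all zeros with a warning. A single-sample matrix is an
    error: a spread cannot be estimated.
    """
    if expr.shape[1] < 2:
        raise ValueError("z-scoring needs >= 2 samples")
    values = expr.to_numpy(dtype=float)  # raises on non-numeric cells
    means = values.mean(axis=1, keepdims=True)
    centered = values - means
    if center_only:
        return pd.DataFrame(centered, index=expr.index, columns=expr.columns)
    sds = values.std(axis=1, ddof=0, keepdims=True)
    flat = (sds == 0).ravel()
    if flat.any():
        logger.warning(
            "%d constant gene row(s) z-scored to all zeros: %s",
            int(flat.sum()),
            list(expr.index[flat][:5]),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sds == 0, 0.0, centered / np.where(sds == 0, 1.0, sds))
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def apply_signature(
    model: SignatureModel, normalized_expr: pd.DataFrame, strict: bool = True
) -> pd.Series:
    """Per-sample risk score: the coefficient-weighted sum of gene z-scores.

    In strict mode every model gene must be a row of the matrix; in lenient
    mode absent genes contribute 0 (their z is imputed as the mean) with a
    warning.
    """
    missing = [g for g in model.genes if g not in normalized_expr.index]
    if missing:
        if strict:
            raise KeyError(
                f"expression matrix lacks {len(missing)} model gene(s): {missing}"
            )
        logger.warning(
            "%d model gene(s) absent; imputing z=0 for %s", len(missing), missing
        )
    scores = pd.Series(0.0, index=normalized_expr.columns, name="cedg_score")
    for gene, coef in zip(model.genes, model.coefficients):
        if gene in normalized_expr.index:
            scores = scores + coef * normalized_expr.loc[gene]
    scores.name = "cedg_score"
    return scores


def risk_stratify(scores: pd.Series) -> pd.DataFrame:
    """Split samples at the median score: > median is high risk, else low.

    Samples tied exactly at the median land in the low-risk group. Returns
    a frame with ``cedg_score`` and ``risk_group`` indexed by sample.
    """
    if len(scores) < 2:
        raise ValueError("risk stratification needs >= 2 samples")
    cutoff = float(scores.median())
    groups = np.where(scores > cutoff, "high", "low")
    return pd.DataFrame(
        {"cedg_score": scores, "risk_group": groups}, index=scores.index
    )


def score_expression(
    expr: pd.DataFrame,
    model: SignatureModel = CEDG17,
    strict: bool = True,
    center_only: bool = False,
) -> pd.DataFrame:
    """Convenience: z-score, apply the signature, stratify by the median."""
    z = zscore(expr, center_only=center_only)
    return risk_stratify(apply_signature(model, z, strict=strict))
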