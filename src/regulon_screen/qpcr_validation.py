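"""Relative qPCR quantification and the validation / complementation rules.

Expression of each target gene is standardized to a housekeeping reference
measured in the same strain and replicate (the classic delta-Ct method):
``R = E**(-(Ct_gene - Ct_ref))`` with amplification efficiency ``E``
(default 2, perfect doubling).  Replicates are averaged on the delta-Ct
(log) scale.  A candidate is called regulator-dependent when wild type
exceeds the null mutant by at least ``tau_val``-fold (default 4), and
strongly production-dependent at ``tau_strong`` (default 11).  The
complementation rule calls expression "restored" when both the wild type
and the complemented mutant exceed the null mutant by the threshold fold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import CtTable

__all__ = [
    "relative_expression",
    "fold_change",
    "fold_and_validate",
    "complementation_call",
    "RESTORED",
    "NOT_RESTORED",
]

RESTORED = "restored"
NOT_RESTORED = "not_restored"


def relative_expression(
    ct: CtTable, reference_gene: str | None = None, efficiency: float = 2.0
) -> pd.DataFrame:
    """Reference-standardized relative expression per (gene, strain).

    Per replicate, ``delta_Ct = Ct_gene - Ct_ref``; replicates are averaged
    on the delta-Ct scale and ``R = efficiency**(-mean delta_Ct)``.

    Returns a frame indexed by (gene, strain) with columns ``rel_expr``,
    ``sd_dct`` (replicate SD of delta-Ct), ``n_reps``.
    """
    reference_gene = reference_gene or ct.reference_gene
    if reference_gene is None:
        raise ValueError("no reference gene specified")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must be > 1")
    data = ct.data
    ref = data[data["gene"] == reference_gene].set_index(["strain", "replicate"])["ct"]
    rows = []
    for (gene, strain), sub in data[data["gene"] != reference_gene].groupby(["gene", "strain"]):
        dcts = []
        for _, row in sub.iterrows():
            key = (strain, row["replicate"])
            if key not in ref.index:
                raise ValueError(
                    f"reference gene {reference_gene!r} not measured for strain "
                    f"{strain!r} replicate {row['replicate']!r}"
                )
            dcts.append(row["ct"] - ref.loc[key])
        dcts = np.asarray(dcts, dtype=float)
        rows.append(
            {
                "gene": gene,
                "strain": strain,
                "rel_expr": float(efficiency ** (-dcts.mean())),
                "sd_dct": float(dcts.std(ddof=1)) if len(dcts) > 1 else 0.0,
                "n_reps": len(dcts),
            }
        )
    return pd.DataFrame(rows).set_index(["gene", "strain"])


def fold_change(rel: pd.DataFrame, gene: str, strain_a: str, strain_b: str) -> float:
    """Fold decrease of strain_b relative to strain_a: R_A / R_B."""
    try:
        r_a = rel.loc[(gene, strain_a), "rel_expr"]
        r_b = rel.loc[(gene, strain_b), "rel_expr"]
    except KeyError as exc:
        raise ValueError(f"gene {gene!r} not measured in strain {exc.args[0]!r}") from exc
    return float(r_a / r_b)


def fold_and_validate(
    rel: pd.DataFrame,
    strain_wt: str,
    strain_null: str,
    strain_act: str | None = None,
    tau_val: float = 4.0,
    tau_strong: float = 11.0,
) -> pd.DataFrame:
    """Validation calls for every gene measured in the required strains.

    ``fold_soxr`` is the fold decrease of the regulator-null mutant versus
    wild type; a gene is regulator-dependent iff ``fold_soxr >= tau_val``.
    When a production-deficient strain is given, ``fold_act`` and the
    production-dependence calls (at ``tau_val``, strongly at
    ``tau_strong``) are added.
    """
    genes = sorted({g for (g, _s) in rel.index})
    rows = []
    for gene in genes:
        fold_soxr = fold_change(rel, gene, strain_wt, strain_null)
        row = {
            "gene": gene,
            "fold_soxr": fold_soxr,
            "soxr_dependent": fold_soxr >= tau_val,
        }
        if strain_act is not None:
            fold_act = fold_change(rel, gene, strain_wt, strain_act)
            row["fold_act"] = fold_act
            row["act_dependent"] = fold_act >= tau_val
            row["act_strong"] = fold_act >= tau_strong
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def complementation_call(
    rel: pd.DataFrame,
    gene: str,
    strain_wt: str,
    strain_null: str,
    strain_comp: str,
    tau: float = 4.0,
) -> str:
    """Call whether complementation restores a gene's expression.

    ``restored`` iff both the wild type and the complemented strain exceed
    the null mutant by at least ``tau``-fold.  This covers both published
    failure modes: a complemented strain stuck at null-mutant levels, and
    a gene whose expression never depended on the regulator in the first
    place (all three strains similar).
    """
    f_wt = fold_change(rel, gene, strain_wt, strain_null)
    f_comp = fold_change(rel, gene, strain_comp, strain_null)
    return RESTORED if (f_wt >= tau and f_comp >= tau) else NOT_RESTORED
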