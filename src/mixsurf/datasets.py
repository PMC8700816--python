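"""Bundled example dataset: a 17-run essential-oil nanoemulsion study.

A published formulation-optimization experiment on the lipid phase of an
oil-in-water nanoemulsion: an I-optimal mixture design over three
essential oils (cumin, carvi, coriander) with four measured responses per
run — Sauter mean droplet diameter d3.2 (um), DPPH antioxidant IC50
(mg/mL), and viable colony counts of B. subtilis and E. coli (CFU/mL).
The design has 12 distinct blends and 5 pure-error degrees of freedom
(centroid x4, two binary blends x2 each).

The published analysis modeled sqrt(d3.2) and sqrt(IC50) with the full
reduced-cubic (9-term) Scheffe polynomial, the B. subtilis count with an
8-term reduced cubic, and the E. coli count with the 6-term quadratic;
those specifications ship here as :func:`published_models`.
"""

from __future__ import annotations

import io as _io

import pandas as pd

from .design import Blend, MixtureDesign
from .models import ModelSpec, parse_term

__all__ = [
    "COMPONENTS",
    "RESPONSES",
    "OPTIMAL_BLEND",
    "load_nanoemulsion",
    "published_models",
    "published_anova_terms",
]

COMPONENTS = ["EO_CU", "EO_CA", "EO_CO"]

#: response column -> units
RESPONSES = {
    "d32_um": "um",
    "ic50_mg_ml": "mg/mL",
    "b_subtilis_cfu_ml": "CFU/mL",
    "e_coli_cfu_ml": "CFU/mL",
}

#: optimal lipid-phase composition reported by the study (fractions)
OPTIMAL_BLEND = Blend((0.1907, 0.6009, 0.2084))

# 17 runs as printed: fractions, d3.2 (um), PDI, IC50 (mg/mL),
# B. subtilis (CFU x 1e5/mL), E. coli (CFU x 1e6/mL).  The +/- SD columns
# of the source table accompany the counts; they are carried as-is and
# used by no computation.
_CSV = """\
run,EO_CU,EO_CA,EO_CO,d32_um,pdi,ic50_mg_ml,b_subtilis_1e5,b_subtilis_sd,e_coli_1e6,e_coli_sd
1,0.333333,0.333333,0.333333,1.37,0.61,8.99,2.366,214,4.85,110
2,0,0.5,0.5,1.55,0.63,9.126,1.732,105,3.05,468
3,0.166667,0.666667,0.166667,0.505,0.15,7,1.105,95,0.4,432
4,0.5,0,0.5,2.599,0.56,11.578,10.333,133,30.12,502
5,0.5,0,0.5,2.597,0.58,11.578,9.666,283,40.19,166
6,0,0,1,4.67,0.97,15.789,24.333,972,60.24,1031
7,0,0.5,0.5,1.55,0.51,9.15,0.577,246,2.745,333
8,0.333333,0.333333,0.333333,1.1,0.57,8.5,1.154,548,8.8,301
9,1,0,0,2.1,0.55,10.59,6.060,865,29.3,1146
10,0.166667,0.166667,0.666667,3.31,0.84,13.56,6.666,147,24.35,194
11,0.666667,0.333333,0,1.8,0.444,9.986,1.666,617,15.7,386
12,0.333333,0.333333,0.333333,1.38,0.441,8.9,2.082,658,12.766,45
13,0,1,0,1.67,0.60,9.865,1.732,223,12.933,227
14,0.666667,0,0.333333,2,0.79,10.056,2.645,542,23.066,11
15,0.333333,0.666667,0,0.523,0.23,7.3,0.333,690,0.51,180
16,0.5,0.5,0,1.3,0.53,8.76,2.081,630,13.666,20
17,0.333333,0.333333,0.333333,1.36,0.52,8.99,1.154,158,9.166,27
"""


def _table() -> pd.DataFrame:
    return pd.read_csv(_io.StringIO(_CSV), dtype={"run": str})


def load_nanoemulsion() -> tuple[MixtureDesign, pd.DataFrame]:
    """The 17-run design and its response table.

    Returns ``(design, responses)`` where ``responses`` is indexed by run
    id with columns ``d32_um``, ``ic50_mg_ml``, ``b_subtilis_cfu_ml``,
    ``e_coli_cfu_ml`` (counts converted to absolute CFU/mL) and ``pdi``
    (data only, not modeled).
    """
    t = _table()
    design = MixtureDesign(
        runs=[Blend(row) for row in t[COMPONENTS].to_numpy()],
        run_ids=t["run"].tolist(),
        component_names=list(COMPONENTS),
    )
    resp = pd.DataFrame(
        {
            "d32_um": t["d32_um"].to_numpy(),
            "ic50_mg_ml": t["ic50_mg_ml"].to_numpy(),
            "b_subtilis_cfu_ml": t["b_subtilis_1e5"].to_numpy() * 1e5,
            "e_coli_cfu_ml": t["e_coli_1e6"].to_numpy() * 1e6,
            "pdi": t["pdi"].to_numpy(),
        },
        index=pd.Index(t["run"], name="run"),
    )
    return design, resp


_FULL9 = ["A", "B", "C", "AB", "AC", "BC", "AB(A-B)", "AC(A-C)", "BC(B-C)"]


def published_models() -> dict[str, ModelSpec]:
    """The four model specifications of the published regression equations."""
    def spec(response, names, transform):
        return ModelSpec(
            response=response,
            terms=[parse_term(n) for n in names],
            transform=transform,
            units=RESPONSES[response],
        )

    return {
        "d32_um": spec("d32_um", _FULL9, "sqrt"),
        "ic50_mg_ml": spec("ic50_mg_ml", _FULL9, "sqrt"),
        "b_subtilis_cfu_ml": spec(
            "b_subtilis_cfu_ml",
            ["A", "B", "C", "AB", "AC", "BC", "AC(A-C)", "BC(B-C)"],
            "identity",
        ),
        "e_coli_cfu_ml": spec(
            "e_coli_cfu_ml", ["A", "B", "C", "AB", "AC", "BC"], "identity"
        ),
    }


def published_anova_terms() -> dict[str, list[str]]:
    """Term sets of the published ANOVA tables.

    These differ from :func:`published_models` only for d3.2, whose ANOVA
    dropped the AC(A-C) source (8 terms, residual df 9).
    """
    return {
        "d32_um": ["A", "B", "C", "AB", "AC", "BC", "AB(A-B)", "BC(B-C)"],
        "ic50_mg_ml": list(_FULL9),
        "b_subtilis_cfu_ml": ["A", "B", "C", "AB", "AC", "BC", "AC(A-C)", "BC(B-C)"],
        "e_coli_cfu_ml": ["A", "B", "C", "AB", "AC", "BC"],
    }
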