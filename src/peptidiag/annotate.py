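"""Annotated-peptide parsing, theoretical mass computation and
observed-mass matching.

Annotation strings come in three dialects commonly emitted by proteomics
search engines:

* bare sequence                        ``NRGDSTFESK``
* dot-flanked preceding/following residues  ``R.MLLADQGQSWK.A``
* bracket-flanked flanks               ``[P].TSAHGNVAEGETKPD.[P]``

Theoretical masses (monoisotopic and average, neutral or singly protonated)
are computed from the standard amino-acid composition; observed MALDI m/z
values of serum peptides routinely deviate from the theoretical mass by
more than 0.1 Da, so matching is tolerance-based and tries all four mass
conventions, reporting the best.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from pyteomics import mass as _pmass

__all__ = [
    "AnnotatedPeptide",
    "parse_annotation",
    "format_annotation",
    "peptide_mass",
    "match_observed",
    "MassMatch",
    "REFERENCE_BIOMARKERS",
    "reference_biomarker_table",
]

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

PROTON_MASS = 1.00727646688

_FLANKED = re.compile(
    r"^(?:\[(?P<nb>[A-Z-])\]|(?P<n>[A-Z-]))\."
    r"(?P<core>[A-Z]+)"
    r"\.(?:\[(?P<cb>[A-Z-])\]|(?P<c>[A-Z-]))$"
)


@dataclass
class AnnotatedPeptide:
    raw: str
    core_sequence: str
    n_term_flank: str | None = None
    c_term_flank: str | None = None
    bracketed: bool = False
    gene: str | None = None
    accession: str | None = None
    observed_mass: float | None = None

    @property
    def length(self) -> int:
        return len(self.core_sequence)


def parse_annotation(raw: str, **meta) -> AnnotatedPeptide:
    """Parse any of the three annotation dialects into its parts.

    Raises ``ValueError`` naming the offending character if the core
    sequence contains anything outside the 20 standard residues.
    """
    raw = raw.strip()
    if not raw:
        raise ValueError("empty annotation string")
    m = _FLANKED.match(raw)
    if m:
        core = m.group("core")
        nf = m.group("nb") or m.group("n")
        cf = m.group("cb") or m.group("c")
        bracketed = m.group("nb") is not None
    else:
        core, nf, cf, bracketed = raw, None, None, False
    bad = set(core) - VALID_RESIDUES
    if bad:
        raise ValueError(
            f"illegal residue character(s) {sorted(bad)} in annotation {raw!r}"
        )
    return AnnotatedPeptide(
        raw=raw, core_sequence=core, n_term_flank=nf, c_term_flank=cf,
        bracketed=bracketed, **meta,
    )


def format_annotation(p: AnnotatedPeptide) -> str:
    """Inverse of :func:`parse_annotation` (identity on all dialects)."""
    if p.n_term_flank is None and p.c_term_flank is None:
        return p.core_sequence
    if p.bracketed:
        return f"[{p.n_term_flank}].{p.core_sequence}.[{p.c_term_flank}]"
    return f"{p.n_term_flank}.{p.core_sequence}.{p.c_term_flank}"


def peptide_mass(
    core_sequence: str, mode: str = "monoisotopic", protonated: bool = False
) -> float:
    """Theoretical peptide mass in Da: residue masses + water, plus one
    proton for the singly charged [M+H]+ convention."""
    if not core_sequence:
        raise ValueError("empty sequence")
    bad = set(core_sequence) - VALID_RESIDUES
    if bad:
        raise ValueError(f"illegal residue character(s) {sorted(bad)}")
    if mode == "monoisotopic":
        m = _pmass.calculate_mass(sequence=core_sequence)
    elif mode == "average":
        m = _pmass.calculate_mass(sequence=core_sequence, average=True)
    else:
        raise ValueError(f"unknown mass mode {mode!r}")
    return float(m) + (PROTON_MASS if protonated else 0.0)


@dataclass
class MassMatch:
    peptide: AnnotatedPeptide
    mode: str
    protonated: bool
    theoretical: float
    delta_ppm: float


def match_observed(
    observed_mz: float,
    candidates: list[AnnotatedPeptide],
    tol_ppm: float,
) -> list[MassMatch]:
    """Candidates whose theoretical mass (any of the four conventions) falls
    within ``tol_ppm`` of the observed value, best convention per candidate,
    sorted by |Δppm|."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    out: list[MassMatch] = []
    for cand in candidates:
        best: MassMatch | None = None
        for mode in ("monoisotopic", "average"):
            for prot in (False, True):
                theo = peptide_mass(cand.core_sequence, mode=mode, protonated=prot)
                dppm = (observed_mz - theo) / theo * 1e6
                if abs(dppm) <= tol_ppm and (best is None or abs(dppm) < abs(best.delta_ppm)):
                    best = MassMatch(cand, mode, prot, theo, dppm)
        if best is not None:
            out.append(best)
    return sorted(out, key=lambda m: abs(m.delta_ppm))


# Reference serum biomarker peptides for the thyroid-cancer panel: observed
# MALDI m/z, annotated sequence, the length printed in the source table,
# gene symbol and UniProt accession.  One row (GRAMD1B) prints a length that
# contradicts its own sequence (53 vs 49 residues); it is kept verbatim so
# that the inconsistency is detectable downstream.
REFERENCE_BIOMARKERS: list[dict] = [
    dict(mass=3241.91, annotation="NRGDSTFESKSYKMADEAGSEADHEGTHST",
         reported_length=30, gene="FGA", accession="P02671"),
    dict(mass=3444.79, annotation="SETESRGSESGIFTNTKESSSHHPGIAEFPSR",
         reported_length=32, gene="FGA", accession="P02671"),
    dict(mass=5904.80,
         annotation="SSSSSSSSSSSSSSSVHEPKMDALIIPVTMEVPCDSRGQRMWWAFLASSMVTFF",
         reported_length=54, gene="KCNMA1", accession="Q12791"),
    dict(mass=5920.47,
         annotation="SCVLVLLVILNMMLFYKLWMLEYTTQTLTAWQGLRLQERLPQSQTEWAQ",
         reported_length=53, gene="GRAMD1B", accession="Q3KR37"),
    dict(mass=1515.83, annotation="[P].TSAHGNVAEGETKPD.[P]",
         reported_length=15, gene="HPX", accession="P02790"),
    dict(mass=1568.81, annotation="[G].FKSHALQLNNRQI.[R]",
         reported_length=13, gene="C4A", accession="P0C0L4"),
    dict(mass=1866.20, annotation="[L].FEKKSLEDKTERELL.[E]",
         reported_length=15, gene="F2", accession="P00734"),
    dict(mass=2991.70, annotation="R.MLLADQGQSWKEEVVTVETWQEGSLK.A",
         reported_length=26, gene="GSTP1", accession="P09211"),
    dict(mass=3381.09, annotation="LATVYVDVLKDSGRDYVSQFEGSALGKQLNL",
         reported_length=31, gene="APOA1", accession="P02647"),
    dict(mass=3770.10, annotation="A.GAAGSRMNFRPGVLSSRQLGLPGPPDVPDHAAYHPF.R",
         reported_length=36, gene="ITIH4", accession="B2RMS9"),
    dict(mass=5337.66,
         annotation="[K].SSSYSKQFTSSTSYNRGDSTFESKSYKMADEAGSEADHEGTHSTKRGHA.[K]",
         reported_length=49, gene="FGA", accession="P02671"),
]


def reference_biomarker_table() -> pd.DataFrame:
    """The reference panel with parsed lengths and a consistency flag for
    the printed length column."""
    rows = []
    for r in REFERENCE_BIOMARKERS:
        p = parse_annotation(r["annotation"], gene=r["gene"],
                             accession=r["accession"], observed_mass=r["mass"])
        rows.append({
            "mass": r["mass"],
            "annotation": r["annotation"],
            "gene": r["gene"],
            "accession": r["accession"],
            "reported_length": r["reported_length"],
            "parsed_length": p.length,
            "length_consistent": p.length == r["reported_length"],
        })
    return pd.DataFrame(rows)
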