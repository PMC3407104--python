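"""Published reference parameter estimates for the two studied molecules.

IFNGFP is the interferon-alpha/GFP fusion; IFNGFPApo additionally carries
apolipoprotein A-I, which slows hepatic synthesis (longer transit chain
traversal), adds a peripheral distribution compartment, and raises the
serum exposure.  Transcription kinetics are shared between the molecules
(same plasmid backbone); protein and brain kinetics are molecule specific.

These sets serve as simulation ground truth for the synthetic study design
and as sensible starting points for refitting.
"""

from __future__ import annotations

from .params import (
    BrainParams,
    HepaticProteinParams,
    ISGParams,
    KineticParameterSet,
    PeripheralExchange,
    TranscriptionParams,
)

__all__ = [
    "reference_transcription",
    "ifngfp_parameters",
    "ifngfpapo_parameters",
    "reference_parameters",
    "isg_parameters",
    "ISG_GENES",
]

ISG_GENES = ("ISG15", "OAS")


def reference_transcription() -> TranscriptionParams:
    """Shared plasmid transcription kinetics (both molecules)."""
    return TranscriptionParams(
        k_nunc=1.60, k_int=0.112, k_s1=1080.0, k_s2=2.96, k_deg=2.12
    )


def ifngfp_parameters() -> KineticParameterSet:
    """Reference kinetic estimates for the IFNGFP fusion (no peripheral)."""
    return KineticParameterSet(
        molecule="IFNGFP",
        transcription=reference_transcription(),
        protein=HepaticProteinParams(
            k_s=769.0, k_d=22.4, k_tran=1.45,
            k_ls=120.0, k_sl=0.406, k_sb=1.08e-6, n_transit=3,
        ),
        brain=BrainParams(k_e=0.118),
    )


def ifngfpapo_parameters() -> KineticParameterSet:
    """Reference kinetic estimates for the IFNGFPApo fusion (peripheral)."""
    return KineticParameterSet(
        molecule="IFNGFPApo",
        transcription=reference_transcription(),
        protein=HepaticProteinParams(
            k_s=53600.0, k_d=0.0773, k_tran=0.266,
            k_ls=1720.0, k_sl=0.420, k_sb=3.75e-5, n_transit=3,
            peripheral=PeripheralExchange(k_sp=1.54, k_ps=0.00994),
        ),
        brain=BrainParams(k_e=0.509),
    )


def reference_parameters() -> dict[str, KineticParameterSet]:
    """Both reference kinetic parameter sets keyed by molecule label."""
    sets = (ifngfp_parameters(), ifngfpapo_parameters())
    return {p.molecule: p for p in sets}


# Dynamic (ISG turnover) reference estimates.  Liver synthesis is saturable
# and shared between molecules; brain synthesis is linear with a
# molecule-specific efficiency and a shared degradation rate per gene.
# The liver ISG15 degradation rate is taken equal to the brain estimate for
# the same transcript (the published liver value is not recoverable); see
# docs/methods.md.
_ISG_LIVER = {
    "ISG15": ISGParams(k_s_isg=491.0, k_d_isg=0.127, ifn50=151.0),
    "OAS": ISGParams(k_s_isg=0.0366, k_d_isg=1.18, ifn50=255.0),
}
_ISG_BRAIN = {
    ("ISG15", "IFNGFP"): ISGParams(k_s_isg=2.05e-3, k_d_isg=0.127),
    ("ISG15", "IFNGFPApo"): ISGParams(k_s_isg=6.08e-4, k_d_isg=0.127),
    ("OAS", "IFNGFP"): ISGParams(k_s_isg=7.37e-5, k_d_isg=0.101),
    ("OAS", "IFNGFPApo"): ISGParams(k_s_isg=2.45e-5, k_d_isg=0.101),
}


def isg_parameters(gene: str, organ: str, molecule: str | None = None) -> ISGParams:
    """Reference turnover parameters for one gene in one organ.

    Liver parameters are molecule independent (shared saturable model);
    brain parameters require the molecule label (linear model with
    per-molecule synthesis efficiency).
    """
    if gene not in ISG_GENES:
        raise KeyError(f"unknown ISG gene {gene!r}; known: {ISG_GENES}")
    if organ == "liver":
        return _ISG_LIVER[gene]
    if organ == "brain":
        if molecule is None:
            raise ValueError("brain ISG parameters are molecule specific; pass molecule=")
        return _ISG_BRAIN[(gene, molecule)]
    raise KeyError(f"unknown organ {organ!r}; expected 'liver' or 'brain'")
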