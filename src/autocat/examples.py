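"""Packaged example networks: the central-carbon autocatalytic cycles.

Each function builds a small lumped network for one of the classic
autocatalytic motifs of central carbon metabolism.  These are the canonical
worked examples for the detector and the formal verifier:

* glyoxylate shunt -- one internal malate plus two external acetyl-CoA
  become two malate per turn;
* PTS glucose import -- one pep imports a glucose whose catabolism returns
  two pep;
* glycolysis ATP autocatalysis ("turbo design") -- 2 ATP invested in the
  priming phase, 4 ATP returned in the payoff phase;
* lumped CBB carboxylation -- 5 five-carbon sugars plus 5 CO2 give 6
  five-carbon sugars.
"""

from __future__ import annotations

from .netmodel import MetabolicNetwork, Metabolite, Reaction

__all__ = [
    "glyoxylate_network",
    "pts_network",
    "glycolysis_atp_network",
    "cbb_lumped_network",
]


def glyoxylate_network() -> MetabolicNetwork:
    """Glyoxylate cycle lumped to two reactions over {mal, icit, accoa}.

    ``mal_to_icit`` assimilates one acetyl-CoA while converting malate to
    isocitrate; ``icit_split`` assimilates a second acetyl-CoA and splits
    isocitrate into two malate.  Net per turn: +1 malate, -2 acetyl-CoA.
    """
    return MetabolicNetwork(
        metabolites=[
            Metabolite("mal", "malate"),
            Metabolite("icit", "isocitrate"),
            Metabolite("accoa", "acetyl-CoA", is_external=True),
        ],
        reactions=[
            Reaction("mal_to_icit", {"mal": 1, "accoa": 1}, {"icit": 1}),
            Reaction("icit_split", {"icit": 1, "accoa": 1}, {"mal": 2}),
        ],
    )


def pts_network() -> MetabolicNetwork:
    """Phosphotransferase-system glucose assimilation closed by glycolysis.

    ``pts`` imports external glucose using one pep; ``glycolysis`` (lumped
    lower glycolysis) regenerates two pep from the imported sugar.
    """
    return MetabolicNetwork(
        metabolites=[
            Metabolite("pep", "phosphoenolpyruvate"),
            Metabolite("g6p", "glucose-6-phosphate"),
            Metabolite("glc", "glucose", is_external=True),
        ],
        reactions=[
            Reaction("pts", {"pep": 1, "glc": 1}, {"g6p": 1}),
            Reaction("glycolysis", {"g6p": 1}, {"pep": 2}),
        ],
    )


def glycolysis_atp_network() -> MetabolicNetwork:
    """ATP autocatalysis in glycolysis, lumped to priming + payoff.

    ``priming`` invests 2 ATP to split glucose into two triose phosphates;
    ``payoff`` converts one triose phosphate to pyruvate yielding 2 ATP.
    Applying priming once and payoff twice consumes 2 ATP and produces 4.
    """
    return MetabolicNetwork(
        metabolites=[
            Metabolite("atp", "ATP"),
            Metabolite("g3p", "triose phosphate"),
            Metabolite("glc", "glucose", is_external=True),
            Metabolite("adp", "ADP", is_external=True),
            Metabolite("pyr", "pyruvate", is_external=True),
        ],
        reactions=[
            Reaction("priming", {"glc": 1, "atp": 2}, {"g3p": 2, "adp": 2}),
            Reaction("payoff", {"g3p": 1, "adp": 2}, {"pyr": 1, "atp": 2}),
        ],
    )


def cbb_lumped_network() -> MetabolicNetwork:
    """Calvin-Benson-Bassham cycle lumped to carboxylation + regeneration.

    ``carboxylation`` fixes 5 CO2 onto 5 five-carbon sugars, giving 10
    three-carbon units; ``regeneration`` rearranges the 10 trioses back into
    6 five-carbon sugars.  One turn therefore consumes 5 C5 and produces 6 --
    the cycle's 5:6 autocatalytic stoichiometry, a gain of one C5 per turn.
    """
    return MetabolicNetwork(
        metabolites=[
            Metabolite("c5", "five-carbon sugar pool"),
            Metabolite("c3", "three-carbon (triose) pool"),
            Metabolite("co2", "carbon dioxide", is_external=True),
        ],
        reactions=[
            Reaction("carboxylation", {"c5": 5, "co2": 5}, {"c3": 10}),
            Reaction("regeneration", {"c3": 10}, {"c5": 6}),
        ],
    )
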