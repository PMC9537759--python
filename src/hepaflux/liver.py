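"""Reference integrated liver network: glucose + APAP + cysteine metabolism.

The network couples three pathways in one hepatocyte:

* glucose metabolism - GLUT2 transport, glycolysis, gluconeogenesis
  (cytosolic and mitochondrial PEPCK routes, glucose-6-phosphatase in the
  endoplasmic reticulum) and glycogen turnover, with the
  fructose-2,6-bisphosphate signal switching the PFK1/FBP1 futile cycle;
* APAP metabolism - glucuronidation (UGT, consuming UDP-glucuronic acid
  made from UDP-glucose), sulfation (SULT, consuming PAPS), CYP2E1
  oxidation to NAPQI, GSH conjugation and protein-adduct formation;
* cysteine/GSH metabolism - cysteine uptake feeding GSH synthesis, which
  detoxifies NAPQI; the free protein thiol pool is the adduct target.

UDP-glucuronic acid is the crosstalk node: it is produced from the
glycogenic intermediate pool (G1P -> UDP-glucose -> UDP-GA), so the
nutritional state and gluconeogenic enzyme activities control how much
glucuronidation capacity is available for the drug.

Structure: 34 balanced species (+3 blood boundary species), 47 reactions
split into 27 dynamic (rate-law) and 20 static (pseudo-steady-state)
reactions; the partition yields 13 dynamic-only species and 21 static
species.  Zonation is expressed as 13 Vmax overrides that differ between
the periportal and pericentral profiles.  All kinetic parameters are
calibrated (provenance noted in the document metadata): they were chosen
to reproduce the published zonation orderings and pathway-contribution
tables rather than transcribed from a kinetic database.
"""

from __future__ import annotations

from .document import MetaboliteSpec, ModelDocument, ReactionSpec
from .ratelaws import Modifier, RateLaw

CYT = "cytosol"
ER = "endoplasmic_reticulum"
MITO = "mitochondria"
BLOOD = "blood"

#: fasting / feeding external glucose (mM)
FASTING_GLUCOSE = 4.0
FEEDING_GLUCOSE = 11.0
#: APAP administration rates (mM/h): none / moderate / excessive
APAP_RATES = (0.0, 0.5, 6.0)
#: dosing window (h)
APAP_DURATION = 0.5

DOSING_REACTION = "v_APAP_in"
GLUT2 = "v_GLUT2"

#: APAP elimination pathways used for contribution accounting
PATHWAY_FLUXES = {
    "glucuronidation": "v_UGT",
    "sulfation": "v_Sulf",
    "gsh_conjugation": "v_GSHT",
    "protein_adducts": "v_NAPQI_adduct",
}


def _mm(vmax, substrates, km, modifiers=(), products=()):
    params = {"Vmax": vmax}
    if isinstance(km, dict):
        params.update({f"Km_{s}": v for s, v in km.items()})
    else:
        params["Km"] = km
    return RateLaw("michaelis_menten", params, tuple(substrates), tuple(products),
                   tuple(modifiers))


def _rmm(vmax, substrates, products, kms, keq=1.0):
    params = {"Vmax": vmax, "keq": keq}
    params.update({f"Km_{s}": v for s, v in kms.items()})
    return RateLaw("reversible_michaelis_menten", params, tuple(substrates),
                   tuple(products))


def _hill(vmax, substrate, s50, n):
    return RateLaw("hill", {"Vmax": vmax, "S50": s50, "n": n}, (substrate,))


def _ma(k, substrates):
    return RateLaw("mass_action", {"k": k}, tuple(substrates))


def build_reference_model() -> ModelDocument:
    """Assemble the calibrated two-zone reference liver document."""

    species = [
        # blood boundary species (schedule-driven, not balanced)
        MetaboliteSpec("glc_ext", "blood glucose", BLOOD, 5.0, boundary=True),
        MetaboliteSpec("lac_ext", "blood lactate", BLOOD, 1.0, boundary=True),
        MetaboliteSpec("cys_ext", "blood cysteine", BLOOD, 0.2, boundary=True),
        # cytosolic glucose metabolism
        MetaboliteSpec("glc", "glucose", CYT, 5.0),
        MetaboliteSpec("g6p", "glucose-6-phosphate", CYT, 0.25),
        MetaboliteSpec("f6p", "fructose-6-phosphate", CYT, 0.25),
        MetaboliteSpec("f16bp", "fructose-1,6-bisphosphate", CYT, 0.02),
        MetaboliteSpec("f26bp", "fructose-2,6-bisphosphate", CYT, 0.01),
        MetaboliteSpec("dhap", "dihydroxyacetone phosphate", CYT, 0.05),
        MetaboliteSpec("gap", "glyceraldehyde-3-phosphate", CYT, 0.02),
        MetaboliteSpec("bpg", "1,3-bisphosphoglycerate", CYT, 0.01),
        MetaboliteSpec("pg3", "3-phosphoglycerate", CYT, 0.1),
        MetaboliteSpec("pep", "phosphoenolpyruvate", CYT, 0.1),
        MetaboliteSpec("pyr", "pyruvate", CYT, 0.1),
        MetaboliteSpec("lac", "lactate", CYT, 1.0),
        MetaboliteSpec("oaa", "oxaloacetate", CYT, 0.01),
        MetaboliteSpec("mal", "malate", CYT, 0.3),
        MetaboliteSpec("g1p", "glucose-1-phosphate", CYT, 0.25),
        MetaboliteSpec("udp_glc", "UDP-glucose", CYT, 0.3),
        MetaboliteSpec("udp_ga", "UDP-glucuronic acid", CYT, 0.3),
        MetaboliteSpec("glycogen", "glycogen (glucosyl units)", CYT, 200.0),
        # mitochondria
        MetaboliteSpec("pyr_m", "pyruvate (mito)", MITO, 0.1),
        MetaboliteSpec("oaa_m", "oxaloacetate (mito)", MITO, 0.01),
        MetaboliteSpec("mal_m", "malate (mito)", MITO, 0.3),
        MetaboliteSpec("pep_m", "phosphoenolpyruvate (mito)", MITO, 0.05),
        # endoplasmic reticulum
        MetaboliteSpec("g6p_er", "glucose-6-phosphate (ER)", ER, 0.25),
        # APAP branch
        MetaboliteSpec("apap", "acetaminophen", CYT, 0.0),
        MetaboliteSpec("apap_glu", "APAP-glucuronide", CYT, 0.0),
        MetaboliteSpec("apap_sul", "APAP-sulfate", CYT, 0.0),
        MetaboliteSpec("napqi", "NAPQI", CYT, 0.0),
        MetaboliteSpec("apap_gsh", "APAP-GSH conjugate", CYT, 0.0),
        MetaboliteSpec("adduct", "NAPQI-protein adducts", CYT, 0.0),
        MetaboliteSpec("so4", "inorganic sulfate", CYT, 0.3),
        MetaboliteSpec("paps", "PAPS (sulfate donor)", CYT, 0.1),
        # cysteine / glutathione branch
        MetaboliteSpec("cys", "cysteine", CYT, 0.2),
        MetaboliteSpec("gsh", "glutathione", CYT, 2.0),
        MetaboliteSpec("protsh", "free protein thiols", CYT, 1.0),
    ]

    dyn: list[ReactionSpec] = [
        # --- transport -----------------------------------------------------
        ReactionSpec(
            GLUT2, {"glc": 1}, "dynamic", "glucose transporter 2",
            _rmm(55.0, ["glc_ext"], ["glc"], {"glc_ext": 17.0, "glc": 17.0}),
        ),
        ReactionSpec(
            "v_MCT", {"lac": 1}, "dynamic", "lactate transporter",
            _rmm(30.0, ["lac_ext"], ["lac"], {"lac_ext": 2.0, "lac": 2.0}),
        ),
        ReactionSpec(
            "v_CysT", {"cys": 1}, "dynamic", "cysteine transporter",
            _rmm(10.0, ["cys_ext"], ["cys"], {"cys_ext": 0.2, "cys": 0.2}),
        ),
        ReactionSpec(
            DOSING_REACTION, {"apap": 1}, "dynamic", "APAP administration",
            RateLaw("zero_order", {"rate": 0.0}),
        ),
        # --- glycolysis / gluconeogenesis bottlenecks ----------------------
        ReactionSpec(
            "v_GK", {"glc": -1, "g6p": 1}, "dynamic", "glucokinase",
            _hill(9.0, "glc", 8.0, 1.7),
        ),
        ReactionSpec(
            "v_G6P_ER", {"g6p_er": -1, "glc": 1}, "dynamic",
            "glucose-6-phosphate phosphatase (ER)",
            _mm(8.0, ["g6p_er"], 0.5),
        ),
        ReactionSpec(
            "v_PFK1", {"f6p": -1, "f16bp": 1}, "dynamic", "phosphofructokinase-1",
            _mm(6.0, ["f6p"], 0.3,
                modifiers=[Modifier("f26bp", "activation", {"a": 4.0, "Ka": 0.01})]),
        ),
        ReactionSpec(
            "v_FBP1", {"f16bp": -1, "f6p": 1}, "dynamic", "fructose-1,6-bisphosphatase",
            _mm(8.0, ["f16bp"], 0.05,
                modifiers=[Modifier("f26bp", "inhibition", {"Ki": 0.005})]),
        ),
        ReactionSpec(
            "v_PFK2", {"f6p": -1, "f26bp": 1}, "dynamic", "phosphofructokinase-2",
            _mm(0.1, ["f6p"], 0.3),
        ),
        ReactionSpec(
            "v_FBP2", {"f26bp": -1, "f6p": 1}, "dynamic", "fructose-2,6-bisphosphatase",
            _mm(0.09, ["f26bp"], 0.01),
        ),
        ReactionSpec(
            "v_ALD", {"f16bp": -1, "dhap": 1, "gap": 1}, "dynamic", "aldolase",
            _rmm(12.0, ["f16bp"], ["dhap", "gap"],
                 {"f16bp": 0.05, "dhap": 1.0, "gap": 1.0}, keq=0.1),
        ),
        ReactionSpec(
            "v_PK", {"pep": -1, "pyr": 1}, "dynamic", "pyruvate kinase",
            _hill(12.0, "pep", 0.3, 1.5),
        ),
        ReactionSpec(
            "v_PEPCK", {"oaa": -1, "pep": 1}, "dynamic", "PEPCK (cytosol)",
            _mm(6.0, ["oaa"], 0.01),
        ),
        ReactionSpec(
            "v_LDH", {"pyr": -1, "lac": 1}, "dynamic", "lactate dehydrogenase",
            _rmm(20.0, ["pyr"], ["lac"], {"pyr": 0.5, "lac": 2.0}, keq=10.0),
        ),
        # --- glycogen / UDP-sugar branch -----------------------------------
        ReactionSpec(
            "v_GS", {"udp_glc": -1, "glycogen": 1}, "dynamic", "glycogen synthase",
            _mm(1.0, ["udp_glc"], 0.012,
                modifiers=[Modifier("glc", "activation_hill",
                                    {"a": 1.17, "Ka": 8.57, "n": 8.0})]),
        ),
        ReactionSpec(
            "v_GP", {"glycogen": -1, "g1p": 1}, "dynamic", "glycogen phosphorylase",
            _mm(25.0, ["glycogen"], 200.0,
                modifiers=[Modifier("glc", "inhibition", {"Ki": 10.0})]),
        ),
        ReactionSpec(
            "v_UGP", {"g1p": -1, "udp_glc": 1}, "dynamic",
            "UTP-glucose-1-phosphate uridylyltransferase",
            _mm(5.0, ["g1p"], 0.02,
                modifiers=[Modifier("udp_glc", "inhibition", {"Ki": 1.04})]),
        ),
        # --- APAP metabolism ----------------------------------------------
        ReactionSpec(
            "v_UGT", {"apap": -1, "udp_ga": -1, "apap_glu": 1}, "dynamic",
            "APAP glucuronidation (UGT)",
            _mm(2.5, ["apap", "udp_ga"], {"apap": 1.371, "udp_ga": 0.184}),
        ),
        ReactionSpec(
            "v_Sulf", {"apap": -1, "paps": -1, "apap_sul": 1}, "dynamic",
            "APAP sulfation (SULT)",
            _mm(1.53, ["apap", "paps"], {"apap": 2.325, "paps": 0.05}),
        ),
        ReactionSpec(
            "v_CYP450", {"apap": -1, "napqi": 1}, "dynamic",
            "CYP2E1 oxidation to NAPQI",
            _mm(2.79, ["apap"], 7.636),
        ),
        ReactionSpec(
            "v_GSHT", {"napqi": -1, "gsh": -1, "apap_gsh": 1}, "dynamic",
            "NAPQI-GSH conjugation",
            _mm(1.002, ["napqi", "gsh"], {"napqi": 0.005, "gsh": 0.485}),
        ),
        ReactionSpec(
            "v_NAPQI_adduct", {"napqi": -1, "protsh": -1, "adduct": 1}, "dynamic",
            "protein adduct formation",
            _ma(1.099, ["napqi", "protsh"]),
        ),
        ReactionSpec(
            "v_APAPglu_ex", {"apap_glu": -1}, "dynamic", "APAP-glucuronide export",
            _ma(1.0, ["apap_glu"]),
        ),
        ReactionSpec(
            "v_APAPsul_ex", {"apap_sul": -1}, "dynamic", "APAP-sulfate export",
            _ma(1.0, ["apap_sul"]),
        ),
        ReactionSpec(
            "v_APAPgsh_ex", {"apap_gsh": -1}, "dynamic", "APAP-GSH conjugate export",
            _ma(1.0, ["apap_gsh"]),
        ),
        # --- glutathione ---------------------------------------------------
        ReactionSpec(
            "v_GSH_syn", {"cys": -1, "gsh": 1}, "dynamic", "GSH synthesis",
            _mm(7.0, ["cys"], 0.1,
                modifiers=[Modifier("gsh", "inhibition", {"Ki": 3.0})]),
        ),
        ReactionSpec(
            "v_GSH_deg", {"gsh": -1}, "dynamic", "GSH turnover",
            _ma(0.482, ["gsh"]),
        ),
    ]

    stat: list[ReactionSpec] = [
        ReactionSpec("v_G6PT", {"g6p": -1, "g6p_er": 1}, "static",
                     "G6P transport into ER"),
        ReactionSpec("v_PGI", {"g6p": -1, "f6p": 1}, "static",
                     "phosphoglucose isomerase"),
        ReactionSpec("v_PGM", {"g6p": -1, "g1p": 1}, "static", "phosphoglucomutase"),
        ReactionSpec("v_TPI", {"dhap": -1, "gap": 1}, "static",
                     "triose-phosphate isomerase"),
        ReactionSpec("v_GAPDH", {"gap": -1, "bpg": 1}, "static",
                     "glyceraldehyde-3-phosphate dehydrogenase"),
        ReactionSpec("v_PGK", {"bpg": -1, "pg3": 1}, "static", "phosphoglycerate kinase"),
        ReactionSpec("v_ENO", {"pg3": -1, "pep": 1}, "static",
                     "phosphoglycerate mutase + enolase"),
        ReactionSpec("v_PyrT", {"pyr": -1, "pyr_m": 1}, "static",
                     "mitochondrial pyruvate carrier"),
        ReactionSpec("v_PDH", {"pyr_m": -1}, "static",
                     "pyruvate dehydrogenase (TCA entry)"),
        ReactionSpec("v_PC", {"pyr_m": -1, "oaa_m": 1}, "static", "pyruvate carboxylase"),
        ReactionSpec("v_PEPCKmito", {"oaa_m": -1, "pep_m": 1}, "static",
                     "PEPCK (mitochondria)"),
        ReactionSpec("v_PEPT", {"pep_m": -1, "pep": 1}, "static", "PEP export from mito"),
        ReactionSpec("v_MDHm", {"oaa_m": -1, "mal_m": 1}, "static",
                     "malate dehydrogenase (mito)"),
        ReactionSpec("v_MalT", {"mal_m": -1, "mal": 1}, "static",
                     "malate shuttle transport"),
        ReactionSpec("v_MDHc", {"mal": -1, "oaa": 1}, "static",
                     "malate dehydrogenase (cytosol)"),
        ReactionSpec("v_CS", {"oaa_m": -1}, "static", "citrate synthase (TCA drain)"),
        ReactionSpec("v_UGDH", {"udp_glc": -1, "udp_ga": 1}, "static",
                     "UDP-glucose dehydrogenase"),
        ReactionSpec("v_SO4_up", {"so4": 1}, "static", "sulfate supply"),
        ReactionSpec("v_PAPSS", {"so4": -1, "paps": 1}, "static", "PAPS synthetase"),
        ReactionSpec("v_ProtSH_syn", {"protsh": 1}, "static",
                     "protein thiol pool turnover"),
    ]

    # 13 zonation-dependent Vmax values.  Pericentral: glucose uptake and
    # glycolysis, UDP-glucose synthesis, CYP2E1 and UGT run higher;
    # periportal: gluconeogenesis (FBP1, PEPCK, G6Pase), sulfation and GSH
    # synthesis run higher.
    zones = {
        "periportal": {
            (GLUT2, "Vmax"): 45.0,
            ("v_GK", "Vmax"): 6.0,
            ("v_PK", "Vmax"): 8.0,
            ("v_FBP2", "Vmax"): 0.06,
            ("v_ALD", "Vmax"): 8.0,
            ("v_UGP", "Vmax"): 2.222,
            ("v_CYP450", "Vmax"): 2.182,
            ("v_UGT", "Vmax"): 2.025,
            ("v_FBP1", "Vmax"): 12.0,
            ("v_PEPCK", "Vmax"): 9.0,
            ("v_G6P_ER", "Vmax"): 12.0,
            ("v_Sulf", "Vmax"): 2.372,
            ("v_GSH_syn", "Vmax"): 14.0,
        },
        "pericentral": {
            (GLUT2, "Vmax"): 65.0,
            ("v_GK", "Vmax"): 12.0,
            ("v_PK", "Vmax"): 16.0,
            ("v_FBP2", "Vmax"): 0.12,
            ("v_ALD", "Vmax"): 16.0,
            ("v_UGP", "Vmax"): 4.450,
            ("v_CYP450", "Vmax"): 3.391,
            ("v_UGT", "Vmax"): 3.009,
            ("v_FBP1", "Vmax"): 4.0,
            ("v_PEPCK", "Vmax"): 3.0,
            ("v_G6P_ER", "Vmax"): 4.0,
            ("v_Sulf", "Vmax"): 0.684,
            ("v_GSH_syn", "Vmax"): 0.338,
        },
    }

    reactions = dyn + stat
    provenance = {
        f"{r.id}.{p}": "calibrated"
        for r in reactions
        if r.rate_law is not None
        for p in r.rate_law.parameters
    }
    doc = ModelDocument(
        metabolites=species,
        reactions=reactions,
        zones=zones,
        metadata={
            "name": "reference zonated liver model (glucose + APAP + Cys)",
            "version": "1.0",
            "units": {"concentration": "mM", "time": "h", "rate": "mM/h"},
            "provenance": provenance,
        },
    )
    return doc
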