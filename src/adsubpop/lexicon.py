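"""Medication-name normalization and pharmacologic class annotation.

Free-text medication logs spell the same substance many ways ('vit. c',
'Vitamin C', 'vitamin_c').  Normalization case-folds, strips punctuation
and maps synonyms to a canonical snake_case token.  Brand and generic names
are deliberately kept distinct (Aricept ≠ donepezil) so brand-specific
patterns remain visible; the class map then lets both roll up to one
pharmacologic class token for class-level mining.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

_PUNCT_RE = re.compile(r"[^\w\s]")
_WS_RE = re.compile(r"[\s_]+")

#: raw/spelling variant -> canonical token (applied after basic cleanup)
DEFAULT_SYNONYMS: dict[str, str] = {
    "vit c": "vitamin_c", "vit. c": "vitamin_c", "vitamin c": "vitamin_c",
    "ascorbic acid": "ascorbic_acid",
    "vit d": "vitamin_d", "vit. d": "vitamin_d", "vitamin d": "vitamin_d",
    "vitamin d3": "vitamin_d", "cholecalciferol": "vitamin_d",
    "vit e": "vitamin_e", "vit. e": "vitamin_e", "vitamin e": "vitamin_e",
    "alpha tocopherol": "vitamin_e",
    "vit b12": "vitamin_b12", "vit. b12": "vitamin_b12",
    "vitamin b12": "vitamin_b12", "cyanocobalamin": "vitamin_b12",
    "donepezil hcl": "donepezil", "donepezil hydrochloride": "donepezil",
    "memantine hcl": "memantine",
    "sertraline hcl": "sertraline",
    "atorvastatin calcium": "atorvastatin",
}

#: canonical token -> pharmacologic class token
DEFAULT_CLASSES: dict[str, str] = {
    # AD symptomatic therapies
    "aricept": "cholinesterase_inhibitor",
    "donepezil": "cholinesterase_inhibitor",
    "exelon": "cholinesterase_inhibitor",
    "rivastigmine": "cholinesterase_inhibitor",
    "razadyne": "cholinesterase_inhibitor",
    "galantamine": "cholinesterase_inhibitor",
    "namenda": "nmda_receptor_antagonist",
    "memantine": "nmda_receptor_antagonist",
    # antidepressants
    "zoloft": "serotonin_reuptake_inhibitor",
    "sertraline": "serotonin_reuptake_inhibitor",
    "prozac": "serotonin_reuptake_inhibitor",
    "fluoxetine": "serotonin_reuptake_inhibitor",
    "celexa": "serotonin_reuptake_inhibitor",
    "citalopram": "serotonin_reuptake_inhibitor",
    "lexapro": "serotonin_reuptake_inhibitor",
    "escitalopram": "serotonin_reuptake_inhibitor",
    # anti-hyperlipidemia
    "simvastatin": "hmg_coa_reductase_inhibitor",
    "zocor": "hmg_coa_reductase_inhibitor",
    "lipitor": "hmg_coa_reductase_inhibitor",
    "atorvastatin": "hmg_coa_reductase_inhibitor",
    "crestor": "hmg_coa_reductase_inhibitor",
    "rosuvastatin": "hmg_coa_reductase_inhibitor",
    "pravastatin": "hmg_coa_reductase_inhibitor",
    "lovastatin": "hmg_coa_reductase_inhibitor",
    # vitamins / supplements
    "vitamin_c": "antioxidant_vitamin",
    "ascorbic_acid": "antioxidant_vitamin",
    "vitamin_e": "antioxidant_vitamin",
    "vitamin_d": "vitamin_d_supplement",
    "vitamin_b12": "b_vitamin",
    "folate": "b_vitamin",
    "folic acid": "b_vitamin",
    "multivitamin": "multivitamin",
}


@dataclass
class DrugLexicon:
    """Synonym map (raw → canonical) and class map (canonical → class)."""

    synonyms: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SYNONYMS))
    classes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CLASSES))

    @classmethod
    def from_csv(cls, path) -> "DrugLexicon":
        """Load an extension lexicon (columns: raw, canonical, class)."""
        df = pd.read_csv(path, dtype=str)
        lex = cls()
        for _, row in df.iterrows():
            raw = _basic_clean(row["raw"])
            lex.synonyms[raw.replace("_", " ")] = row["canonical"]
            if isinstance(row.get("class"), str) and row["class"]:
                lex.classes[row["canonical"]] = row["class"]
        return lex


def _basic_clean(raw: str) -> str:
    text = _PUNCT_RE.sub(" ", raw.casefold())
    return _WS_RE.sub(" ", text).strip()


def normalize_drug_name(raw: str, lexicon: DrugLexicon | None = None) -> str:
    """Normalize a free-text drug name to its canonical snake_case token.

    Unknown names pass through cleaned (with a warning) rather than being
    dropped, so novel substances still participate in mining.
    """
    if not raw or not str(raw).strip():
        raise ValueError("empty drug name")
    lex = lexicon or DrugLexicon()
    cleaned = _basic_clean(str(raw))
    token = lex.synonyms.get(cleaned, cleaned.replace(" ", "_"))
    if cleaned not in lex.synonyms and token not in lex.classes:
        logger.warning("unknown drug name %r normalized to %r", raw, token)
    return token


def annotate_class(token: str, lexicon: DrugLexicon | None = None) -> str:
    """Return the pharmacologic class token, or ``"unclassified"``."""
    lex = lexicon or DrugLexicon()
    return lex.classes.get(token, "unclassified")
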