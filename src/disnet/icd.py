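"""ICD-10 / KCD chapter lookup for 3-character category codes.

KCD (the Korean modification of ICD-10) adds Korean-medicine codes in the
U20-U99 range; everything else follows the standard ICD-10 chapter blocks.
"""

from __future__ import annotations

__all__ = ["icd10_chapter", "CHAPTER_NAMES"]

CHAPTER_NAMES = {
    "I": "Infectious and parasitic diseases",
    "II": "Neoplasms",
    "III": "Blood and immune mechanism",
    "IV": "Endocrine, nutritional and metabolic",
    "V": "Mental and behavioural disorders",
    "VI": "Nervous system",
    "VII": "Eye and adnexa",
    "VIII": "Ear and mastoid process",
    "IX": "Circulatory system",
    "X": "Respiratory system",
    "XI": "Digestive system",
    "XII": "Skin and subcutaneous tissue",
    "XIII": "Musculoskeletal system",
    "XIV": "Genitourinary system",
    "XV": "Pregnancy, childbirth and the puerperium",
    "XVI": "Perinatal period conditions",
    "XVII": "Congenital malformations",
    "XVIII": "Symptoms, signs and abnormal findings",
    "XIX": "Injury, poisoning, external causes",
    "XX": "External causes of morbidity",
    "XXI": "Factors influencing health status",
    "KR": "Korean medicine (KCD U codes)",
}

_SINGLE_LETTER = {
    "E": "IV", "F": "V", "G": "VI", "I": "IX", "J": "X", "K": "XI",
    "L": "XII", "M": "XIII", "N": "XIV", "O": "XV", "P": "XVI",
    "Q": "XVII", "R": "XVIII", "Z": "XXI",
}


def icd10_chapter(code: str) -> str:
    """Chapter (Roman numeral, or ``"KR"``/``"unknown"``) of a 3-character
    category code, using the standard letter+number blocks (A00-B99 -> I,
    C00-D48 -> II, D50-D89 -> III, H00-H59 -> VII, H60-H95 -> VIII, ...)."""
    if len(code) < 3:
        return "unknown"
    letter = code[0].upper()
    try:
        num = int(code[1:3])
    except ValueError:
        return "unknown"
    if letter in ("A", "B"):
        return "I"
    if letter == "C":
        return "II"
    if letter == "D":
        return "II" if num <= 48 else "III"
    if letter == "H":
        return "VII" if num <= 59 else "VIII"
    if letter in ("S", "T"):
        return "XIX"
    if letter in ("V", "W", "X", "Y"):
        return "XX"
    if letter == "U":
        return "KR"
    return _SINGLE_LETTER.get(letter, "unknown")
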