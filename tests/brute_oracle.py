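"""Independent brute-force evaluation of the diagnostic criteria.

Deliberately coded straight off the printed criteria as flat boolean
expressions over plain dicts (True/False flags, ints), sharing no code with
the engine. Used only as an oracle in truth-table and property tests.
"""

CHILD_CAUSE_ORDER = ["meningitis", "pneumonia", "malnutrition", "diarrhea", "hiv_aids", "malaria"]
NEONATE_CAUSE_ORDER = ["septicemia", "meningitis", "pneumonia", "congenital_malformation"]


def child_fires(cause, s):
    if cause == "malaria":
        return (
            s["fever"]
            and (s["convulsions"] or s["unconscious"])
            and not s["stiff_neck"]
            and not s["bulging_fontanelle"]
        ) or (
            s["fever"]
            and (
                (s["convulsions"] and not s["unconscious"])
                or s["difficulty_breathing"]
                or s["blood_in_urine"]
                or s["pale_body"]
                or s["lack_of_blood"]
            )
        )
    if cause == "hiv_aids":
        return s["mouth_sore"] or s["yellow_eyes"] or s["wasting"]
    if cause == "pneumonia":
        return (
            s["cough"]
            and s["cough_duration_days"] < 22
            and s["fever"]
            and s["difficulty_breathing"]
        )
    if cause == "meningitis":
        return (s["stiff_neck"] or s["bulging_fontanelle"]) and (
            s["fever"] or s["convulsions"] or s["unconscious"]
        )
    if cause == "diarrhea":
        return s["stools_per_day"] > 2
    if cause == "malnutrition":
        return (
            s["wasting"]
            or (s["weight_loss"] and s["weight_loss_duration_days"] >= 14)
            or (s["swelling"] and (s["rash"] or s["hair_color_change"]))
        )
    raise KeyError(cause)


def neonate_fires(cause, s):
    if cause == "septicemia":
        items = [
            s["stopped_suckling"],
            s["fever"] or s["cold_to_touch"],
            s["lethargic_or_unresponsive"] or s["unconscious"],
            s["convulsions"],
            s["vomiting"],
            s["skin_pustules"],
        ]
        return sum(items) >= 2
    if cause == "meningitis":
        return s["fever"] and s["convulsions"]
    if cause == "pneumonia":
        return s["cough"] and s["difficulty_breathing"]
    if cause == "congenital_malformation":
        return s["deformity"]
    raise KeyError(cause)


def multi(age_group, s):
    fires = child_fires if age_group == "child" else neonate_fires
    order = CHILD_CAUSE_ORDER if age_group == "child" else NEONATE_CAUSE_ORDER
    return {c for c in order if fires(c, s)}


def single(age_group, s):
    fires = child_fires if age_group == "child" else neonate_fires
    order = CHILD_CAUSE_ORDER if age_group == "child" else NEONATE_CAUSE_ORDER
    for c in order:
        if fires(c, s):
            return c
    return "other"
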