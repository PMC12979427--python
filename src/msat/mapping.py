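"""Rule-based mapping of MedDRA terms onto TCM functional systems.

A MedDRA Preferred Term (PT) together with its System Organ Class (SOC) is
assigned one or more of 16 TCM functional systems (Zang organs with the
Pericardium counted among them, six Fu organs, Body Surface, Chong-Ren
Meridians, Meridians and Collaterals, Qi-Blood-Fluid). The dual-input logic
matters: within the gastrointestinal SOC, "Jaundice" belongs to the Liver
system while "Nausea" belongs to Spleen and Stomach, so exact-PT rules take
precedence over SOC defaults. Terms matching no rule are surfaced as
unmapped, never silently dropped.

The shipped default rule file covers the PTs used in the worked validation
examples plus SOC-level defaults; it is editable data, not code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class MeddraTerm:
    pt: str
    soc: str

    def __post_init__(self):
        if not self.pt:
            raise ValueError("pt must be non-empty")


@dataclass
class TcmRuleSet:
    """Ordered PT/SOC -> functional-system rules over a fixed vocabulary."""

    systems: list[str]
    pt_rules: dict[str, list[str]]
    soc_rules: dict[str, list[str]]

    def __post_init__(self):
        vocab = set(self.systems)
        if len(vocab) != len(self.systems):
            raise ValueError("duplicate system names in vocabulary")
        for kind, rules in (("pt", self.pt_rules), ("soc", self.soc_rules)):
            for key, targets in rules.items():
                unknown = set(targets) - vocab
                if unknown:
                    raise ValueError(
                        f"{kind} rule {key!r} targets unknown system(s) "
                        f"{sorted(unknown)}")
                if not targets:
                    raise ValueError(f"{kind} rule {key!r} has no targets")
        if not self.pt_rules and not self.soc_rules:
            warnings.warn("rule set is empty; all terms will be unmapped",
                          stacklevel=3)


def load_rules(rule_file=None) -> TcmRuleSet:
    """Load a rule set from YAML; with no argument, the shipped default."""
    if rule_file is None:
        text = (resources.files("msat") / "data" / "tcm_rules.yaml").read_text(
            encoding="utf-8")
    else:
        with open(rule_file, encoding="utf-8") as fh:
            text = fh.read()
    obj = yaml.safe_load(text) or {}
    return TcmRuleSet(systems=list(obj.get("systems", [])),
                      pt_rules={str(k): list(v) for k, v in
                                (obj.get("pt_rules") or {}).items()},
                      soc_rules={str(k): list(v) for k, v in
                                 (obj.get("soc_rules") or {}).items()})


def load_pt_to_soc(path=None) -> dict[str, str]:
    """PT -> SOC lookup table from TSV; shipped default with no argument."""
    if path is None:
        with resources.as_file(
                resources.files("msat") / "data" / "pt_to_soc.tsv") as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"pt", "soc"} <= set(df.columns):
        raise ValueError("PT->SOC table must have columns pt, soc")
    return dict(zip(df["pt"], df["soc"]))


def map_term(term: MeddraTerm, rules: TcmRuleSet) -> set[str] | None:
    """Functional systems for a term; None when no rule matches.

    Exact-PT rules win over the SOC default (first match in rule order).
    """
    if term.pt in rules.pt_rules:
        return set(rules.pt_rules[term.pt])
    if term.soc in rules.soc_rules:
        return set(rules.soc_rules[term.soc])
    return None


def format_systems(systems: set[str] | None, rules: TcmRuleSet) -> str:
    """Render a system set in stable vocabulary order, '+'-joined."""
    if systems is None:
        return UNMAPPED
    order = {s: i for i, s in enumerate(rules.systems)}
    return "+".join(sorted(systems, key=lambda s: order[s]))


def map_predictions(prediction_table: pd.DataFrame, rules: TcmRuleSet,
                    pt_to_soc: dict[str, str],
                    pt_column: str = "adr_id") -> pd.DataFrame:
    """Annotate a prediction table with TCM functional systems.

    Rows whose PT is absent from the PT->SOC table, or that match no rule,
    are flagged (``mapping_flag``), never dropped.
    """
    out = prediction_table.copy()
    systems_col = []
    flags = []
    n_missing = 0
    for pt in out[pt_column].astype(str):
        soc = pt_to_soc.get(pt)
        if soc is None:
            n_missing += 1
            systems_col.append(UNMAPPED)
            flags.append("missing_soc")
            continue
        mapped = map_term(MeddraTerm(pt=pt, soc=soc), rules)
        systems_col.append(format_systems(mapped, rules))
        flags.append("ok" if mapped is not None else "unmapped")
    if n_missing:
        warnings.warn(f"{n_missing} prediction row(s) lack a PT->SOC entry",
                      stacklevel=2)
    out["tcm_systems"] = systems_col
    out["mapping_flag"] = flags
    return out
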