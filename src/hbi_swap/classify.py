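"""Beverage classification: food code / label -> one of the eight HBI groups.

Classification is table-driven. The shipped mapping is a miniature
pattern table (longest-prefix match on a normalized label, exact or
prefix match on the food code), standing in for a full food-and-nutrient
database linkage. Unmapped items fail loudly: a silent default would
bias every downstream estimate.

Group conventions:

* sweetened coffee/tea, soda, fruit drinks, energy and sports drinks and
  meal-replacement drinks are sugar-sweetened beverages (SSB);
* non-calorically sweetened drinks, including diet soda and coffee/tea
  with non-caloric sweetener, are DIET;
* milk below 1.5 % fat (and soy/skim) is LOW_FAT_MILK, at or above
  1.5 % fat it is WHOLE_MILK;
* beer, wine and liquor are ALCOHOL.
"""

from __future__ import annotations

from importlib import resources

from .model import BeverageGroup

__all__ = ["ClassificationError", "GroupMapping", "classify_beverage", "default_mapping"]


class ClassificationError(KeyError):
    """A food code / label could not be mapped to a beverage group."""


def _normalize(label: str) -> str:
    return " ".join(label.strip().lower().split())


class GroupMapping:
    """Pattern table mapping labels (and food codes) to beverage groups.

    Label patterns match by longest normalized prefix; food-code patterns
    match exactly or by prefix. Label match takes precedence when a label
    is supplied.
    """

    def __init__(self, label_patterns: dict[str, BeverageGroup], code_patterns: dict[str, BeverageGroup]):
        self._labels = {_normalize(k): v for k, v in label_patterns.items()}
        self._codes = dict(code_patterns)

    @classmethod
    def from_tsv(cls, path_or_buffer) -> "GroupMapping":
        """Load a mapping from TSV columns: kind (label|code), pattern, group."""
        labels: dict[str, BeverageGroup] = {}
        codes: dict[str, BeverageGroup] = {}
        if hasattr(path_or_buffer, "read"):
            text = path_or_buffer.read()
        else:
            with open(path_or_buffer, "r", encoding="utf-8") as fh:
                text = fh.read()
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "kind":  # header
                continue
            if len(parts) != 3:
                raise ValueError(f"mapping line {lineno}: expected 3 tab-separated fields, got {len(parts)}")
            kind, pattern, group = parts
            try:
                g = BeverageGroup(group)
            except ValueError as exc:
                raise ValueError(f"mapping line {lineno}: unknown group {group!r}") from exc
            if kind == "label":
                labels[pattern] = g
            elif kind == "code":
                codes[pattern] = g
            else:
                raise ValueError(f"mapping line {lineno}: kind must be 'label' or 'code', got {kind!r}")
        return cls(labels, codes)

    def classify(self, food_code: str, group_label: str | None = None) -> BeverageGroup:
        if group_label:
            # canonical group names (as written by this package) short-circuit
            try:
                return BeverageGroup(group_label.strip().upper().replace(" ", "_"))
            except ValueError:
                pass
            norm = _normalize(group_label)
            best: tuple[int, BeverageGroup] | None = None
            for pattern, group in self._labels.items():
                if norm.startswith(pattern) and (best is None or len(pattern) > best[0]):
                    best = (len(pattern), group)
            if best is not None:
                return best[1]
        code = str(food_code).strip()
        if code in self._codes:
            return self._codes[code]
        best_code: tuple[int, BeverageGroup] | None = None
        for pattern, group in self._codes.items():
            if code.startswith(pattern) and (best_code is None or len(pattern) > best_code[0]):
                best_code = (len(pattern), group)
        if best_code is not None:
            return best_code[1]
        raise ClassificationError(
            f"unmapped beverage: food_code={food_code!r}, group_label={group_label!r}"
        )


_DEFAULT: GroupMapping | None = None


def default_mapping() -> GroupMapping:
    """The mapping fixture shipped with the package."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("hbi_swap.data").joinpath("beverage_groups.tsv")
        with ref.open("r", encoding="utf-8") as fh:
            _DEFAULT = GroupMapping.from_tsv(fh)
    return _DEFAULT


def classify_beverage(food_code: str, group_label: str | None = None, mapping: GroupMapping | None = None) -> BeverageGroup:
    """Classify one beverage item into exactly one of the eight groups."""
    return (mapping or default_mapping()).classify(food_code, group_label)
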