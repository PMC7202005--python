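"""Bundled per-species comparative tables.

``table1`` holds the published per-species summary (heterochromatin
percentage, inversion status, mean dot-dot distance, oocyte counts,
proportion out, mean dot area) for the 15 surveyed species; ``—``/``n.d.``
entries are transcribed as empty fields and load as NaN. ``table2_pairs``
lists the six closely related, inversion-type-divergent species pairs
with the published Δ and t-test p-values (the p < 2.2 × 10⁻¹⁶ floor is
stored as 2.2e-16). Files are integrity-checked at load.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

__all__ = ["load_table1", "load_table2_pairs", "CLOSE_PAIRS", "SINGLETONS"]

_CHECKSUMS = {
    "table1.csv": "76d0bd83c42c15c6258d3d4bbc6184420a591e6c63a0a80f02b736019a32cfa2",
    "table2_pairs.csv": "bed59ba137977bd122435655d566181e4fdc9ba271c2792bf2a86751c7f16894",
}

#: (polymorphic, monomorphic) abbreviations of the close species pairs.
CLOSE_PAIRS: list[tuple[str, str]] = [
    ("mel", "sim"),
    ("yak", "ere"),
    ("car", "sig"),
    ("hyd", "mea"),
    ("ame", "vir"),
    ("nic", "mul"),
]

#: Species without a close partner, retained as-is under pair-averaging.
SINGLETONS: tuple[str, ...] = ("sec", "pse")


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("karyodot.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(
            f"bundled fixture {name} failed its integrity check "
            f"(sha256 {digest}); reinstall the package"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_table1() -> pd.DataFrame:
    """Per-species summary table (15 species; NaN where not measurable)."""
    df = _read("table1.csv")
    df["has_common_inversions"] = df["has_common_inversions"].astype(bool)
    return df


def load_table2_pairs() -> pd.DataFrame:
    """The six inversion-type-divergent pairs with published Δ and p."""
    return _read("table2_pairs.csv")
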