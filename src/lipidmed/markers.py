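"""Canonical NMR lipidomic marker panel.

The analysis operates on ~61 lipoprotein and lipid measures of the kind
quantified by high-throughput NMR platforms: particle concentrations,
cholesterol and triglyceride content of density/size-specific lipoprotein
subfractions (VLDL, IDL, LDL, HDL), summary lipid concentrations,
apolipoproteins, and mean particle diameters.  Each marker carries a class
tag used by the synthetic-data generator to assign factor loadings and
lifestyle/genetic effect signs.
"""

from __future__ import annotations

_VLDL_SIZES = ["XXL", "XL", "L", "M", "S", "XS"]
_LDL_SIZES = ["L", "M", "S"]
_HDL_SIZES = ["XL", "L", "M", "S"]


def _subfraction_names() -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    for suffix, kind in (("P", "particles"), ("C", "cholesterol"), ("TG", "triglycerides")):
        for s in _VLDL_SIZES:
            out.append((f"{s}-VLDL-{suffix}", "vldl"))
        out.append((f"IDL-{suffix}", "idl"))
        for s in _LDL_SIZES:
            out.append((f"{s}-LDL-{suffix}", "ldl"))
        for s in _HDL_SIZES:
            out.append((f"{s}-HDL-{suffix}", "hdl"))
    return out


#: marker name -> lipoprotein class tag ("vldl", "idl", "ldl", "hdl", "apo", "size")
MARKER_CLASSES: dict[str, str] = dict(
    _subfraction_names()
    + [
        ("VLDL-C", "vldl"),
        ("LDL-C", "ldl"),
        ("HDL-C", "hdl"),
        ("HDL2-C", "hdl"),
        ("HDL3-C", "hdl"),
        ("Remnant-C", "vldl"),
        ("Total-C", "ldl"),
        ("non-HDL-C", "ldl"),
        ("Total-TG", "vldl"),
        ("VLDL-TG", "vldl"),
        ("LDL-TG", "ldl"),
        ("HDL-TG", "hdl"),
        ("Total-P", "ldl"),
        ("ApoA1", "hdl"),
        ("ApoB", "ldl"),
        ("ApoB/ApoA1", "ldl"),
        ("VLDL-D", "size"),
        ("LDL-D", "size"),
        ("HDL-D", "size"),
    ]
)

#: the default 61-marker panel, in reporting order
MARKER_NAMES: list[str] = list(MARKER_CLASSES)

assert len(MARKER_NAMES) == 61
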