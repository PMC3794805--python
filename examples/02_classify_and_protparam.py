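"""Classify proteins into ZIK / MEKK / Raf by signature motif and compute
their theoretical pI and molecular weight.

The three subfamily signatures overlap, so calls use the precedence
ZIK > MEKK > Raf and flag ambiguity. pI is found by bisection on the
Henderson-Hasselbalch net-charge curve (Bjellqvist pK set); Mw sums
average residue masses plus one water.
"""

from kinfamscan.classify import classify_protein
from kinfamscan.protparam import isoelectric_point, molecular_weight
from kinfamscan.seqio import SeqEntry

PAD = "MKVLAWHEDRCQGILFPSTY"
examples = {
    "zik_like": PAD + "GTPEFMAPELY" + PAD,
    "mekk_like": PAD + "GSPAWMAPEV" + PAD,
    "raf_like": PAD + "GTAAYMAPEL" + PAD,
    "overlap": PAD + "GTPAWMAPEV" + PAD,  # satisfies MEKK and Raf
    "no_signature": PAD * 3,
}

for name, seq in examples.items():
    call = classify_protein(SeqEntry(name, "", seq))
    pi = isoelectric_point(seq)
    mw = molecular_weight(seq) / 1000.0
    flag = " (ambiguous)" if call.ambiguous else ""
    print(f"{name:13s} -> {call.subfamily:12s}{flag:12s} "
          f"pI {pi:5.2f}  Mw {mw:6.2f} kDa")
# The "overlap" sequence matches both the MEKK and Raf consensus; the
# most-specific class (MEKK) wins and the ambiguity flag records the
# overlap instead of discarding it.
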