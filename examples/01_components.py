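"""Project raw morphometrics onto the independent components K, I, S.

Builds a two-hemisphere table by hand, maps each row into the log-area
space (log10 At, log10 Ae, log10 T^2) and projects onto the tension,
isometric and shape directions.  K is near-constant across healthy adult
cortices; I tracks size; S tracks shape at fixed size.
"""

import pandas as pd

from foldmorph import components_table

table = pd.DataFrame(
    {
        "subject_id": ["sub01", "sub01"],
        "hemisphere": ["left", "right"],
        "At_mm2": [95_000.0, 97_000.0],   # total pial surface area
        "Ae_mm2": [39_000.0, 40_000.0],   # exposed (envelope) surface area
        "T_mm": [2.50, 2.55],             # mean cortical thickness
    }
)

out = components_table(table, log_columns=True)
print(out[["hemisphere", "logAt", "logAe", "logT2", "K", "I", "S"]].round(4).to_string(index=False))
print()
print("K is the offset log k of the folding scaling law At*sqrt(T) = k*Ae^(5/4);")
print("I sums the three log-areas (pure size); S is the orthogonal shape term.")
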