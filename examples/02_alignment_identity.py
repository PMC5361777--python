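"""Pairwise alignment and the two percent-identity conventions.

A fragment aligned to its full-length transcript is 100% identical under
the shorter-sequence denominator (the redundancy convention) but much lower
under the columns denominator (the conservation convention) because end
gaps inflate the column count.
"""

from tickpi import AlignParams, align, percent_identity

full = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
fragment = full[:20]

result = align(fragment, full, AlignParams(mode="global"))
print(f"score={result.score}  matches={result.matches}  "
      f"columns={result.aligned_columns}  gap_columns={result.gap_columns}")
print("identity (columns)  :", percent_identity(result, "columns"))
print("identity (shorter)  :", percent_identity(result, "shorter"))

local = align("HEAGAWGHEE", "PAWHEAE", AlignParams(mode="local"))
print("\nlocal alignment:")
print(" ", local.aligned_a)
print(" ", local.aligned_b)
print(f"score={local.score}, spans {local.query_span} / {local.subject_span}")
# The shorter convention reads 100.0 here: every fragment residue matches,
# so the fragment would collapse onto the transcript at the 95% threshold.
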