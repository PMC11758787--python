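"""Turn sequences into sentences and model output back into an alignment.

The concat scheme joins the unaligned sequences with pipe tokens; the
spaces scheme reads an alignment column-major, one character per token.
Decoding validates the output: a sentence that mutates, truncates, or
misshapes the input yields a verdict instead of an alignment.
"""

from seq2msa import Msa, SequenceSet, Sentence, decode_spaces, encode_concat, encode_spaces, vocabulary

ss = SequenceSet(["s1", "s2", "s3"], ["AAG", "ACGG", "ACG"])
print("concat input sentence: ", encode_concat(ss).text())

truth = Msa(["s1", "s2", "s3"], ["A-AG", "ACGG", "A-CG"])
target = encode_spaces(truth)
print("spaces target sentence:", target.text())

decoded = decode_spaces(target, ss)
print("decoding the true target reconstructs the alignment:", decoded.rows == truth.rows)

# corrupt one token: the first character of row 2 becomes G
bad = Sentence(["A", "G"] + target.tokens[2:], "spaces", 3)
verdict = decode_spaces(bad, ss)
print(f"corrupted sentence -> valid={verdict.valid}, reason={verdict.reason.value}")

print("pairs vocabulary for 3 DNA sequences:", vocabulary("pairs", "DNA", 3).size, "tokens")
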