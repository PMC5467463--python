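# Chunk grammar: named patterns over POS tags, one rule per line.
# Rules are tried in file order at each position; the longest match wins.
# Tags: DT determiner, JJ adjective, CD number, NN noun, VB finite verb form,
#       VBN participle/past form, BE copula form, MD modal, RB adverb,
#       IN preposition, CC coordination, WDT relative, PUNCT punctuation.
# A PP is formed structurally from an IN immediately followed by an NP;
# a BE not absorbed by a VP is a copula (COP) element.
VP: (MD)? (RB)* (BE)? (RB)* (VB|VBN)+
COP: BE
NP: (DT)? (JJ|CD|NN)* (NN|CD)
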