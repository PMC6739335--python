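# Synthetic 7-node reconstruction of the published toy walkthrough network.
# The original supplementary rule listing is not distributed here; these
# rules were found by randomized search constrained to reproduce every
# fact the main text states about the toy model (see package docs):
#   peel order G then F; fixed-point attractor beta = (1,0,1,1,1,1,0);
#   terminal basin state (0,0,1,0,0,0,0); basin boundary from
#   alpha = (0,0,0,0,1,0,0) exactly {(0,0,1,0,1,0,0)}; C fixed at 1 over
#   the reduced basin with A,B,D,E unfixed; B of indegree 1 via C, so C
#   is the deterministic node; E nondeterministic with deterministic input.
targets, factors
A, B | C
B, !C
C, (!D & !E) | (!A & !D & E) | (A & D & E)
D, !B | C
E, C & (!B | D)
F, A
G, B & !F
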