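# Boolean model of the E. coli lac operon (13 nodes).
# Transcribed from the bistable lac operon Boolean model of Veliz-Cuba &
# Stigler (2011), J. Comput. Biol. 18(6):783-794 (10 internal variables plus
# the three environmental inputs Ge, Le, Lem written as explicit identity
# nodes).
#
# M  = lacZ mRNA                    P  = lac permease
# B  = beta-galactosidase           C  = catabolite activator protein (CAP)
# R  = repressor (high)             Rm = repressor (at least medium)
# A  = allolactose (high)           Am = allolactose (at least medium)
# L  = intracellular lactose (high) Lm = intracellular lactose (at least medium)
# Ge = extracellular glucose        Le = extracellular lactose (high)
# Lem = extracellular lactose (medium)
targets, factors
M, C & !R & !Rm
P, M
B, M
C, !Ge
R, !A & !Am
Rm, (!A & !Am) | R
A, L & B
Am, A | L | Lm
L, P & Le & !Ge
Lm, ((Lem & P) | Le) & !Ge
Ge, Ge
Le, Le
Lem, Lem
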