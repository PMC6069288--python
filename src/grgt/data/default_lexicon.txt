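# Default dictionary shipped with grgt.
# A small, user-replaceable stand-in: real deployments supply their own
# protein-name list and interaction-word grouping via the same format.

[proteins]
PAHX
FKBP52
FKBP12
PAR3alpha
PAR6
P1
P2
P3
CaM
calmodulin
RAF1
MEK1
ERK2
SNF1
GAL4

[interactions]
# lemma<TAB>group  -- words within a group are grammatically interchangeable
interact	assoc
associate	assoc
cooperate	assoc
couple	assoc
bind	bind
attach	bind
conjugate	bind
tether	bind
activate	activate
stimulate	activate
induce	activate
enhance	activate
inhibit	inhibit
suppress	inhibit
repress	inhibit
block	inhibit
regulate	regulate
modulate	regulate
mediate	regulate
control	regulate
phosphorylate	modify
acetylate	modify
methylate	modify
ubiquitinate	modify
target	target
recognize	target
recruit	target
cleave	target

[morphemes]
# suffix<TAB>replacement (empty replacement = bare strip); tried in order
ies	y
ation	ate
ion
ing
ing	e
ed
ed	e
es
s
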