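# WordNet-style noun hypernym chain for "cat" (depth anchors: thing=1,
# animal=3, cat=10) plus a small verb component illustrating per-class roots.
#! source synthetic-fixture
S	n01	noun	entity	that which is perceived to have its own existence
S	n02	noun	thing	a separate and self-contained entity
S	n03	noun	living_thing|animate_thing	a living entity
S	n04	noun	organism|being	a living thing that can act on its own
S	n05	noun	animal|animate_being|beast|creature	a living organism with voluntary movement
S	n06	noun	chordate	animal with a notochord
S	n07	noun	vertebrate|craniate	chordate with a segmented spinal column
S	n08	noun	mammal	warm-blooded vertebrate with hair
S	n09	noun	placental|placental_mammal	mammal with a placenta
S	n10	noun	carnivore	placental mammal that eats flesh
S	n11	noun	feline|felid	lithe-bodied roundheaded carnivore
S	n12	noun	cat|true_cat	feline mammal usually having thick soft fur
S	v01	verb	change	undergo a change
S	v02	verb	close|shut	become closed
S	v03	verb	move	move so as to change position
S	v04	verb	leave|go_forth	go away from a place
S	v05	verb	come out|emerge	come out of
E	n02	n01
E	n03	n01
E	n04	n03
E	n05	n04
E	n06	n05
E	n07	n06
E	n08	n07
E	n09	n08
E	n10	n09
E	n11	n10
E	n12	n11
E	v02	v01
E	v03	v01
E	v04	v03
E	v05	v04
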