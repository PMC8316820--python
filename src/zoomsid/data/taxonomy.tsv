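# Taxonomy used for coarse-group ZooMS calls and for comparison against
# morphological identifications. Edge list: child <TAB> parent <TAB> rank.
#
# "#!member" blocks give the panel-taxon membership of each morphological
# size-class category (bovid body-size classes of eastern African
# zooarchaeology: Size 1 ~ dik-dik/suni, Size 1-2 ~ duiker/klipspringer/
# oribi/small caprine, Size 2 ~ caprine/bushbuck/Thomson's gazelle).
# "#!alias" maps morphological-category vocabulary onto tree nodes.
# "#!display" gives the reporting label for group-level calls.
#
#! alias	caprine	Caprinae
#! alias	bovid	Bovidae
#! alias	mammal	Mammalia
#! alias	vertebrate	Vertebrata
#! alias	indeterminate	Vertebrata
#! display	Caprinae	caprine
#! member	Bovid Size 1	Neotragus moschatus
#! member	Bovid Size 1-2	Capra hircus	Ovis aries	Cephalophus spp.	Philantomba monticola
#! member	Bovid Size 2	Capra hircus	Ovis aries	Cephalophus spp.
#! member	Bovid Size 2-3	Bos spp.
#! member	Mammal Size 2	Capra hircus	Ovis aries	Cephalophus spp.	Philantomba monticola	Suidae
child	parent	rank
Mammalia	Vertebrata	class
Testudines	Vertebrata	order
Artiodactyla	Mammalia	order
Carnivora	Mammalia	order
Primates	Mammalia	order
Bovidae	Artiodactyla	family
Suidae	Artiodactyla	family
Caprinae	Bovidae	subfamily
Bovinae	Bovidae	subfamily
Antilopinae	Bovidae	subfamily
Cephalophinae	Bovidae	subfamily
Capra hircus	Caprinae	species
Ovis aries	Caprinae	species
Bos spp.	Bovinae	genus
Neotragus moschatus	Antilopinae	species
Cephalophus spp.	Cephalophinae	genus
Philantomba monticola	Cephalophinae	species
Canidae	Carnivora	family
Felidae	Carnivora	family
Cercopithecidae	Primates	family
Cercopithecinae	Cercopithecidae	subfamily
Cheloniidae	Testudines	family
Dermochelyidae	Testudines	family
Eretmochelys imbricata	Cheloniidae	species
Dermochelys coriacea	Dermochelyidae	species
Bovid Size 1	Bovidae	size-class
Bovid Size 1-2	Bovidae	size-class
Bovid Size 2	Bovidae	size-class
Bovid Size 2-3	Bovidae	size-class
Mammal Size 2	Mammalia	size-class
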