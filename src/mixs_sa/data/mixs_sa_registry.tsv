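canonical_name	display_name	mixs_id	category	packages	requirements	definition	value_syntax
host_dependence	host dependence	0001315	symbiont_specific	symbiont-associated	symbiont-associated=M	Type of host dependence for the symbiotic host organism to its host.	free_text
type_of_symbiosis	type of symbiosis	0001307	symbiont_specific	symbiont-associated	symbiont-associated=C	Type of biological interaction established between the symbiotic host organism being sampled and its respective host.	free_text
symbiotic_host_organism_life_cycle_type	symbiotic host organism life cycle type	0001300	symbiont_specific	symbiont-associated	symbiont-associated=M	Type of life cycle of the symbiotic host species (the thing being sampled). Simple life cycles occur within a single host, complex ones within multiple different hosts over the course of their normal life cycle.	free_text
host_life_stage	host life stage	0000251	symbiont_specific	symbiont-associated	symbiont-associated=M	Description of life stage of host.	free_text
mode_of_transmission	mode of transmission	0001312	symbiont_specific	symbiont-associated	symbiont-associated=C	The process through which the symbiotic host organism entered the host from which it was sampled.	free_text
route_of_transmission	route of transmission	0001316	symbiont_specific	symbiont-associated	symbiont-associated=O	Description of path taken by the symbiotic host organism being sampled in order to establish a symbiotic relationship with the host (with which it was observed at the time of sampling) via a mode of transmission (specified in mode_transmission).	free_text
host_number_individual	host number individual	0001305	symbiont_specific	symbiont-associated	symbiont-associated=O	Number of symbiotic host individuals pooled at the time of collection.	integer_count
observed_host_symbionts	observed host symbionts	0001309	shared	symbiont-associated;host-associated;human-associated;plant-associated;human-vaginal;human-skin;human-oral;human-gut	symbiont-associated=O;host-associated=O;human-associated=O;plant-associated=O;human-vaginal=O;human-skin=O;human-oral=O;human-gut=O	The taxonomic name of the organism(s) found living in mutualistic, commensalistic, or parasitic symbiosis with the specific host. For cases when the specific host of the sample is a symbiont this field should refer to other organisms it is associated with: e.g.: hyperparasite species X (parasite of the parasite).	taxon_name_list
host_specificity	host specificity	0001308	symbiont_host_relationship	symbiont-associated	symbiont-associated=C	Level of specificity of symbiont-host interaction: e.g. generalist (symbiont able to establish associations with distantly related hosts) or species-specific.	free_text
host_of_the_symbiont_role	host of the symbiont role	0001303	symbiont_host_relationship	symbiont-associated	symbiont-associated=C	Role of the host in the life cycle of the symbiotic organism.	free_text
host_cellular_location	host cellular location	0001313	symbiont_host_relationship	symbiont-associated	symbiont-associated=C	The localization of the symbiotic host organism within the host from which it was sampled: e.g., intracellular if the symbiotic host organism is localized within the cells or extracellular if the symbiotic host organism is localized outside of cells.	free_text
duration_of_association_with_the_host	duration of association with the host	0001299	symbiont_host_relationship	symbiont-associated	symbiont-associated=O	Time spent in host of the symbiotic organism at the time of sampling; relevant scale depends on symbiotic organism and study.	duration
observed_coinfecting_organisms_in_host_of_host	observed coinfecting organisms in host of host	0001310	symbiont_host_relationship	symbiont-associated	symbiont-associated=O	The taxonomic name of any coinfecting organism observed in a symbiotic relationship with the host of the sampled host organism. e.g. where a sample collected from a host trematode species (A) which was collected from a host_of_host fish (B) that was also infected with a nematode (C), the value here would be (C) the nematode {species name} or {common name}. Multiple coinfecting species may be added in a comma-separated list. For listing symbiotic organisms associated with the host (A) use the term Observed host symbiont.	taxon_name_list
host_of_the_symbiotic_host_common_name	host of the symbiotic host common name	0001324	host_of_symbiont	symbiont-associated	symbiont-associated=O	Common name of the host of the symbiotic host organism.	free_text
host_of_the_symbiotic_host_local_environmental_context	host of the symbiotic host local environmental context	0001325	host_of_symbiont	symbiont-associated	symbiont-associated=O	For a symbiotic host organism the local anatomical environment within its host may have causal influences. Report the anatomical entity(s) which are in the direct environment of the symbiotic host organism being sampled and which you believe have significant causal influences on your sample or specimen. For example, if the symbiotic host organism being sampled is an intestinal worm, its local environmental context will be the term for intestine from UBERON (http://uberon.github.io/).	ontology_term
host_of_the_symbiotic_host_environmental_medium	host of the symbiotic host environmental medium	0001326	host_of_symbiont	symbiont-associated	symbiont-associated=O	Report the environmental material(s) immediately surrounding the symbiotic host organism at the time of sampling. This usually will be a tissue or substance type from the host, but may be another material if the symbiont is external to the host. We recommend using classes from the UBERON ontology, but subclasses of 'environmental material' (http://purl.obolibrary.org/obo/ENVO_00010483) may also be used. EnvO documentation about how to use the field: https://github.com/EnvironmentOntology/envo/wiki/Using-ENVO-with-MIxS. Terms from other OBO ontologies are permissible as long as they reference mass/volume nouns (e.g., air, water, blood) and not discrete, countable entities (e.g., intestines, heart).	ontology_term
host_of_the_symbiotic_host_taxon_id	host of the symbiotic host taxon id	0001306	host_of_symbiont	symbiont-associated	symbiont-associated=O	NCBI taxon id of the host of the symbiotic host organism.	taxon_id
host_of_the_symbiotic_host_subject_id	host of the symbiotic host subject id	0001327	host_of_symbiont	symbiont-associated	symbiont-associated=O	A unique identifier by which each host of the symbiotic host organism subject can be referred to, de-identified, e.g. #H14.	free_text
relationship_to_other_samples	relationship to other samples	TBD	core	core	core=C	indicates the direct relationship with another sample from the same Bioproject. Accepted terms are: 'technical replicate of', 'after', 'before', 'next to', 'within', and 'contains'. Can be repeated to reveal relationship to many samples.	relationship_list
biotic_relationship	biotic relationship	0000028	core	core	core=C	Description of relationship(s) between the subject organism and other organism(s) it is associated with. E.g., parasite on species X; mutualist with species Y. The target organism is the subject of the relationship, and the other organism(s) is the object.	free_text
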