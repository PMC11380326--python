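item_id,kind,source_tool,response_domain,merged_from,applicable_animal_baseline,applicable_human_baseline,applicable_animal_treatment,applicable_human_treatment,text,operationalisation
A1a,RQ,ARRIVE,YN,,1,1,1,1,Experimental groups,Clear which groups were subject to which experimental conditions
A1b,RQ,ARRIVE,YN,,1,1,1,1,Unit of analysis,"Clear what the unit of analysis was, including how repeated measures were handled"
A2a,RQ,ARRIVE,YN,A3c;C13a;C16,1,1,1,1,Number of animals (incl. humans),Exact n per group and in total; ranges score N
A2b,RQ,ARRIVE,YN,C7a,1,1,1,1,Sample size calculation,Any a-priori sample size justification suffices
A3a,RQ,ARRIVE,YN,C4a,1,1,1,1,Inclusion criteria,Criteria beyond purely demographic description
A3b,RQ,ARRIVE,YN,,1,1,1,1,Excluded data points,Any explicit statement of exclusions scores Y
A6a,RQ,ARRIVE,YN,C6b,1,1,1,1,All assessed outcome measures,Every assessed outcome explicitly listed
A6b,RQ,ARRIVE,YNI,A10a;C6a,1,1,1,1,Primary outcome,Primary outcome or the one used for the sample-size calculation explicit
A7a,RQ,ARRIVE,YNI,A10b;C12a,1,1,1,1,Statistical methods,Both the methods and the software named
A7b,RQ,ARRIVE,YNI,,1,1,1,1,Statistical assumption tests,Explicit or implicit (results-only) mention of assumption testing
A9a,RQ,ARRIVE,YN,A8a;C5,1,1,1,1,Methods - what was done?,"Enough detail to start a replication: species, strain, age, sex/gender, health status"
A9b,RQ,ARRIVE,YN,C14a,1,1,1,1,When the experiments were performed,Timing known up to the day of the week
A9c,RQ,ARRIVE,YN,,1,1,1,1,Where the experiments were performed,The specific laboratory identifiable
A9d,RQ,ARRIVE,YN,,1,1,1,1,Rationale of the experimental design,Rationale explicit for at least two aspects of the design
A11,RQ,ARRIVE,YN,C1b,1,1,1,1,Abstract completeness,N if any requested element (mostly strain and sex) missing; strain ignored for human studies
A12a,RQ,ARRIVE,YN,C2a,1,1,1,1,Background of the research question,Research question and its relevance understandable
A12b,RQ,ARRIVE,YNI,C2b,1,0,1,1,Animal model relevance,Model validity explicitly described; not scored for human baseline studies
A13,RQ,ARRIVE,YN,,1,1,1,1,Objectives,Objectives clear to both extractors
A14,RQ,ARRIVE,YN,,1,1,1,1,Ethical review,Registration number of the ethics proposal and name of the committee
A15,RQ,ARRIVE,YNI,,1,0,1,0,Housing and husbandry (animal studies),Reasonable idea of the inside of the cages; not scored for human studies
A16a,RQ,ARRIVE,YNI,,1,0,1,0,Refinement (animal studies),Any refinement beyond anaesthesia; not scored for human studies
A16b,RQ,ARRIVE,YN,C19,1,1,1,1,Adverse events,Any mention suffices
A16c,RQ,ARRIVE,YNI,,1,0,1,0,Welfare-related reporting (animal studies),Any mention suffices; not scored for human studies
A17a,RQ,ARRIVE,YN,C22,1,1,1,1,Interpretation of the results,Interpretation explicitly tied to theory / hypotheses / set-up
A17b,RQ,ARRIVE,YN,C20,1,1,1,1,Limitations,One explicit or at least two implicit mentions
A18,RQ,ARRIVE,YNI,C21,1,1,1,1,Generalisability,Extent of external validity described at least implicitly
A20,RQ,ARRIVE,YN,,1,1,1,1,Data availability,Data actually available where stated
A21a,RQ,ARRIVE,YN,,1,1,1,1,Conflicts of interest,Explicit statement of conflicts or of their absence
A21b,RQ,ARRIVE,YN,C25,1,1,1,1,Funding and funder involvement,N if any requested element (mostly funder involvement) missing
C1a,RQ,CONSORT,YN,,1,1,1,1,Type of study in title,Study type identifiable from the title
C3a,RQ,CONSORT,YN,,1,1,1,1,Type of experimental design,Design explicitly mentioned in the paper
C3b,RQ,CONSORT,YN,,1,1,1,1,Protocol violations,Deviations (or their absence) explicitly mentioned
C4b,RQ,CONSORT,YN,,1,1,1,1,Settings of data collection,"Type of setting certain (e.g. laboratory, hospital); more lenient than A9c"
C7b,RQ,CONSORT,YNI,C14b,1,1,1,1,Interim analyses and stopping rules,Any mention; I for single-measurement explicitly short studies
C8b,RQ,CONSORT,YNI,CR1,0,0,1,1,Type of randomisation,Randomisation type mentioned; irrelevant without intervention
C10,RQ,CONSORT,YNI,,0,0,1,1,Allocation roles,Clear who did what in group allocation; irrelevant without intervention
C12b,RQ,CONSORT,YNI,C18,1,1,1,1,Methods for additional analyses,Minimal description of additional analyses; I when a single analysis was prespecified
C15,RQ,CONSORT,YN,,1,1,1,1,Baseline values,Group-level baseline data for at least age/weight and genetics
S1,RoB,SYRCLE,LUHI,A4a;C8a,0,0,1,1,Sequence generation (selection bias),"""Randomly picked from the box"" scores U; I for studies without interventions"
S2,RoB,SYRCLE,LUH,A8b,1,1,1,1,Baseline group differences (selection bias),"L requires comparable baselines for at least age/weight, sex/gender and genetics"
S3,RoB,SYRCLE,LUHI,A5;C9,1,0,1,1,Allocation concealment (selection bias),Allocating investigator adequately blinded for L; I for human studies without interventions
S4,RoB,SYRCLE,LUHI,A4b,1,0,1,0,Animal housing (performance bias),Bias related to housing; I for human studies
S5,RoB,SYRCLE,LUH,CR2;C11a;C11b,1,1,1,1,"Blinding of participants, caregivers and investigators (performance bias)",All investigators performing and/or caring for subjects adequately blinded for L
S6,RoB,SYRCLE,LUH,CR4,1,1,1,1,Order of outcome assessment (detection bias),Bias related to outcome-assessment order or method
S7,RoB,SYRCLE,LUH,,1,1,1,1,Blinding of outcome assessors (detection bias),All outcome assessors adequately blinded for L
S8,RoB,SYRCLE,LUH,CR3;C13b,1,1,1,1,Incomplete outcome data (attrition bias),L requires explicitly complete data or incompleteness equally distributed over groups
S9,RoB,SYRCLE,LUH,A19;CR5;C23;C24,1,1,1,1,Selective outcome reporting (reporting bias),H whenever no protocol was posted (stricter than the source tool)
S10,RoB,SYRCLE,LUH,,1,1,1,1,Other sources of bias,H if methods unclear or concerning at points not covered elsewhere
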