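# default clue lexicon: pattern / dimension / value / kt_context / is_regex
# small, user-replaceable starter list; patterns are lowercased words or phrases
examined	KnowledgeType	Investigation	Investigation
examine	KnowledgeType	Investigation	Investigation
investigate	KnowledgeType	Investigation	Investigation
investigated	KnowledgeType	Investigation	Investigation
investigation	KnowledgeType	Investigation	Investigation
focused	KnowledgeType	Investigation	Investigation
present study	KnowledgeType	Investigation	Investigation
tested the hypothesis	KnowledgeType	Investigation	Investigation
analyzed	KnowledgeType	Investigation	Investigation,Method
studied	KnowledgeType	Investigation	Investigation
demonstrate	KnowledgeType	Analysis	Analysis
demonstrated	KnowledgeType	Analysis	Analysis
indicate	KnowledgeType	Analysis	Analysis
indicates	KnowledgeType	Analysis	Analysis
suggest	KnowledgeType	Analysis	Analysis
suggests	KnowledgeType	Analysis	Analysis
conclude	KnowledgeType	Analysis	Analysis
show	KnowledgeType	Observation	Observation,Analysis
showed	KnowledgeType	Observation	Observation
shown	KnowledgeType	Observation	Observation
observed	KnowledgeType	Observation	Observation
found	KnowledgeType	Observation	Observation
detected	KnowledgeType	Observation	Observation
performed	KnowledgeType	Method	Method
using	KnowledgeType	Method	Method
incubated	KnowledgeType	Method	Method
known	KnowledgeType	Fact	Fact
well known	KnowledgeType	Fact	Fact
established	KnowledgeType	Fact	Fact
suggest	Uncertainty	Uncertain	Analysis
suggests	Uncertainty	Uncertain	Analysis
suggested	Uncertainty	Uncertain	Analysis
may	Uncertainty	Uncertain
might	Uncertainty	Uncertain
could	Uncertainty	Uncertain
possibly	Uncertainty	Uncertain
perhaps	Uncertainty	Uncertain
probably	Uncertainty	Uncertain
possible	Uncertainty	Uncertain
probable	Uncertainty	Uncertain
likely	Uncertainty	Uncertain
appear	Uncertainty	Uncertain
appears	Uncertainty	Uncertain
seem	Uncertainty	Uncertain
seems	Uncertainty	Uncertain
putative	Uncertainty	Uncertain
unclear	Uncertainty	Uncertain
whether	Uncertainty	Uncertain	Investigation
hypothesis	Uncertainty	Uncertain	Investigation
speculate	Uncertainty	Uncertain	Analysis
propose	Uncertainty	Uncertain	Analysis
indicate	Uncertainty	Uncertain	Analysis
previously	KnowledgeSource	Other
previously shown	KnowledgeSource	Other
we previously showed	KnowledgeSource	Other
previous studies	KnowledgeSource	Other
previous work	KnowledgeSource	Other
has been shown	KnowledgeSource	Other
have been shown	KnowledgeSource	Other
it is known	KnowledgeSource	Other	Fact
well established	KnowledgeSource	Other	Fact
has been reported	KnowledgeSource	Other
earlier studies	KnowledgeSource	Other
former work	KnowledgeSource	Other
\[\d+(,\d+)*\]	KnowledgeSource	Other		1
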