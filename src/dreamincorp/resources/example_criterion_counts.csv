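analysis,completed,uncompleted,interrupted
whole_text_overall,20,29,24
whole_text_tidying_the_desk,5,24,31
whole_text_getting_ready_to_leave,25,46,27
forced_choice_allocation,20,28,38
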