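plan,completed,uncompleted,interrupted
setting_the_table,34,25,27
tidying_the_desk,20,37,29
getting_ready_to_leave,32,24,30
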